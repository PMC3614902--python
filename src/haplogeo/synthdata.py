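"""Packaged study fixtures and generative simulators.

The fixture bundle transcribes the study's printed tables: 47 populations
(sample sizes, degree-minute coordinates, altitudes, haplotype lists and
gene diversities) and the 8 x 8 haplotype character matrix (4 substitutions
+ 4 indels over four chloroplast non-coding loci), together with the
dating constants (mu = 1.52e-9 substitutions/site/year, k = 2106 bp,
g = 1 year) and the two haplogroups HPG I = {A,B,C,F,G}, HPG II = {D,E,H}.

Per-population haplotype *counts* are not printed, only the sample size n,
the (alphabetical) haplotype list and the diversity h; ``back_solve_counts``
recovers the unique count multiset consistent with n and h by exhaustive
enumeration, and a ``CountPolicy`` decides which haplotype carries which
count (the table itself carries no frequency information).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

from .diversity import PopulationRecord, gene_diversity
from .haplotypes import (
    GAP,
    AlignedSequences,
    HaplotypeMatrix,
    StepDistanceMatrix,
    VariableSite,
)
from .structure import parse_dms

__all__ = [
    "MU",
    "SEQ_LENGTH",
    "GENERATION_TIME",
    "HPG_I",
    "HPG_II",
    "LOCUS_LENGTHS",
    "COUNT_POLICIES",
    "load_haplotype_matrix",
    "load_population_table",
    "back_solve_counts",
    "rebuild_study_dataset",
    "haplogroup_counts",
    "synth_alignment",
    "simulate_expansion_dataset",
    "planted_partition_dataset",
    "SimulatedSample",
]

MU = 1.52e-9  # substitutions / site / year
SEQ_LENGTH = 2106  # bp, concatenated alignment
GENERATION_TIME = 1.0  # years
HPG_I = ("A", "B", "C", "F", "G")
HPG_II = ("D", "E", "H")
LOCUS_LENGTHS = {"ycf6-psbM": 515, "trnT-trnL": 427, "rps16": 513, "atpI-atpH": 651}
COUNT_POLICIES = ("widespread-major", "alphabetical-major")


def _data_path(name: str):
    return resources.files("haplogeo.data").joinpath(name)


def load_haplotype_matrix() -> HaplotypeMatrix:
    """The 8-haplotype character matrix (canonical labels A-H)."""
    with resources.as_file(_data_path("haplotype_characters.tsv")) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    site_cols = [c for c in df.columns if c != "haplotype"]
    sites = []
    for col in site_cols:
        locus, tag = col.split(":")
        kind = "substitution" if tag.startswith("s") else "indel"
        states = tuple(sorted(set(df[col])))
        # positions are synthetic placeholders; the printed table does not fix them
        sites.append(VariableSite(locus, 1, 1 if kind == "substitution" else 2, kind, states))
    labels = df["haplotype"].tolist()
    states = [tuple(row) for row in df[site_cols].itertuples(index=False)]
    return HaplotypeMatrix(labels, states, sites)


def load_population_table() -> pd.DataFrame:
    """The population table: code, location, coordinates, n, haplotype list, h."""
    with resources.as_file(_data_path("population_table.tsv")) as path:
        df = pd.read_csv(path, sep="\t", dtype={"code": str, "haplotypes": str})
    df["lon"] = df["lon_dms"].map(parse_dms)
    df["lat"] = df["lat_dms"].map(parse_dms)
    df["haplotype_list"] = df["haplotypes"].str.split(",")
    return df


def _round3(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


class CountInconsistencyError(ValueError):
    """No count multiset reproduces the printed diversity."""


def back_solve_counts(n: int, m: int, h: float, unique: bool = True):
    """Count multisets of m haplotypes in n individuals whose unbiased gene
    diversity rounds (half-up, 3 d.p.) to the printed value *h*.

    Returns the unique multiset (descending tuple) when ``unique`` is true,
    raising on zero or multiple solutions; otherwise the list of solutions.
    """
    if n < 2 or not 1 <= m <= n or not 0 <= h < 1:
        raise ValueError("require n >= 2, 1 <= m <= n, 0 <= h < 1")
    solutions = []
    seen = set()
    for comp in _compositions(n, m):
        multiset = tuple(sorted(comp, reverse=True))
        if multiset in seen:
            continue
        seen.add(multiset)
        if _round3(gene_diversity(multiset)) == _round3(h):
            solutions.append(multiset)
    if not unique:
        return solutions
    if not solutions:
        raise CountInconsistencyError(f"no counts give h={h} for n={n}, m={m}")
    if len(solutions) > 1:
        raise CountInconsistencyError(
            f"ambiguous counts for n={n}, m={m}, h={h}: {solutions}"
        )
    return solutions[0]


def _compositions(n: int, m: int):
    """Descending integer compositions of n into m positive parts."""
    if m == 1:
        yield (n,)
        return
    for first in range(n - m + 1, 0, -1):
        for rest in _compositions(n - first, m - 1):
            if rest[0] <= first:
                yield (first, *rest)


def _haplotype_priority(df: pd.DataFrame) -> list[str]:
    """Haplotypes ordered by number of populations carrying them (desc), then label."""
    presence: dict[str, int] = {}
    for haps in df["haplotype_list"]:
        for h in haps:
            presence[h] = presence.get(h, 0) + 1
    return sorted(presence, key=lambda h: (-presence[h], h))


def rebuild_study_dataset(policy: str = "widespread-major") -> list[PopulationRecord]:
    """Reconstruct the 47 population records from the printed table.

    Monomorphic rows carry their single haplotype at count n; polymorphic
    rows get the back-solved count multiset assigned to labels according to
    *policy*: ``widespread-major`` gives larger counts to globally more
    widespread haplotypes, ``alphabetical-major`` to alphabetically earlier
    labels in the row's haplotype list.
    """
    if policy not in COUNT_POLICIES:
        raise ValueError(f"unknown count policy {policy!r}")
    df = load_population_table()
    priority = _haplotype_priority(df)
    rank = {h: i for i, h in enumerate(priority)}
    records = []
    for row in df.itertuples(index=False):
        haps = list(row.haplotype_list)
        if len(haps) == 1:
            counts = {haps[0]: int(row.n)}
        else:
            multiset = back_solve_counts(int(row.n), len(haps), float(row.h))
            if policy == "widespread-major":
                ordered = sorted(haps, key=lambda h: (rank[h], h))
            else:
                ordered = sorted(haps)
            counts = dict(zip(ordered, multiset))
        records.append(
            PopulationRecord(
                code=row.code,
                location=row.location,
                lon=float(row.lon),
                lat=float(row.lat),
                altitude_m=float(row.altitude_m),
                n=int(row.n),
                counts=counts,
                h_printed=float(row.h),
            )
        )
    return records


def haplogroup_counts(
    pops: list[PopulationRecord], group: tuple[str, ...]
) -> dict[str, int]:
    """Pooled haplotype counts over all populations, restricted to *group*."""
    out: dict[str, int] = {}
    for pop in pops:
        for h, c in pop.counts.items():
            if h in group:
                out[h] = out.get(h, 0) + c
    return {h: out[h] for h in sorted(out)}


# ---------------------------------------------------------------------------
# synthetic alignment
# ---------------------------------------------------------------------------


def synth_alignment(
    hm: HaplotypeMatrix,
    assignments: dict[str, list[str]] | None = None,
    locus_lengths: dict[str, int] | None = None,
    seed: int | np.random.Generator | None = 0,
) -> AlignedSequences:
    """Embed a haplotype character matrix into a synthetic alignment.

    Substitution characters become single variable columns and indel
    characters become gap spans (carriers show the motif, non-carriers show
    gaps) embedded in an invariant random background, split into the study's
    four loci by default.  Deterministic for a fixed seed; different seeds
    differ only at background positions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if hm.sites is None:
        raise ValueError("haplotype matrix must carry site metadata")
    lengths = dict(locus_lengths or LOCUS_LENGTHS)
    order = list(lengths)
    # distribute sites to their declared loci (fall back to round-robin)
    per_locus: dict[str, list[int]] = {loc: [] for loc in order}
    for i, site in enumerate(hm.sites):
        loc = site.locus if site.locus in per_locus else order[i % len(order)]
        per_locus[loc].append(i)

    names = list(hm.labels)
    expand = assignments or {}
    indiv_names: list[str] = []
    indiv_hap: list[int] = []
    for k, label in enumerate(names):
        members = expand.get(label) or [label]
        for m in members:
            indiv_names.append(m)
            indiv_hap.append(k)

    loci: dict[str, list[str]] = {}
    for loc in order:
        L = lengths[loc]
        site_ids = per_locus[loc]
        spans = []
        cursor = 0
        # reserve a slot for each site, in order, spaced across the locus
        slot = L // (len(site_ids) + 1) if site_ids else L
        for rank, sid in enumerate(site_ids, start=1):
            site = hm.sites[sid]
            width = 1
            if site.kind == "indel":
                width = max(len(s) for s in {row[sid] for row in hm.states} if s != GAP)
            start = rank * slot - width // 2
            start = max(start, cursor)
            if start + width > L:
                raise ValueError(f"locus {loc!r} too short for its characters")
            spans.append((sid, start, width))
            cursor = start + width
        background = "".join(rng.choice(list("ACGT"), size=L))
        seqs = []
        for k in range(len(names)):
            chars = list(background)
            for sid, start, width in spans:
                state = hm.states[k][sid]
                site = hm.sites[sid]
                if site.kind == "substitution":
                    chars[start] = state
                else:
                    motif = state if state != GAP else GAP * width
                    motif = motif.ljust(width, GAP)[:width]
                    chars[start : start + width] = list(motif)
            seqs.append("".join(chars))
        loci[loc] = [seqs[h] for h in indiv_hap]
    return AlignedSequences(indiv_names, loci, order)


# ---------------------------------------------------------------------------
# coalescent simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedSample:
    """A simulated set of individuals with called haplotypes."""

    individual_haplotypes: list[str]
    populations: list[int]
    counts: dict[str, int] = field(default_factory=dict)
    distances: StepDistanceMatrix | None = None

    def __post_init__(self) -> None:
        if not self.counts:
            for h in self.individual_haplotypes:
                self.counts[h] = self.counts.get(h, 0) + 1


def simulate_expansion_dataset(
    n: int,
    tau: float,
    theta0: float,
    theta1: float,
    n_pops: int = 1,
    migration: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> SimulatedSample:
    """Coalescent sample under sudden expansion with optional subdivision.

    Panmictic Kingman coalescent in mutational (pairwise-difference) time
    with an instantaneous size change from theta0 to theta1 at time tau
    before present, infinite-sites mutation; with ``n_pops > 1`` an
    island-model structured coalescent (per-deme coalescence, symmetric
    migration at rate *migration* per lineage).  Haplotypes are the distinct
    mutation sets; distances count non-shared mutations.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if tau < 0 or theta0 < 0 or theta1 <= 0 or migration < 0 or n_pops < 1:
        raise ValueError("invalid simulation parameters")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    TINY = 1e-12
    deme_of = [i % n_pops for i in range(n)]
    genomes = [0] * n  # bitsets of mutations
    next_bit = 0
    lineages = [([i], deme_of[i]) for i in range(n)]
    born = [0.0] * n  # per-lineage creation time, parallel to lineages
    t = 0.0

    def theta_at(time: float) -> float:
        return theta1 if time < tau else theta0

    def apply_mutations(leafset: list[int], length: float) -> None:
        nonlocal next_bit
        m = rng.poisson(0.5 * length) if length > 0 else 0
        if m:
            mask = ((1 << m) - 1) << next_bit
            next_bit += m
            for leaf in leafset:
                genomes[leaf] |= mask

    while len(lineages) > 1:
        k = len(lineages)
        demes: dict[int, list[int]] = {}
        for idx, (_leaves, dm) in enumerate(lineages):
            demes.setdefault(dm, []).append(idx)
        th = theta_at(t)
        coal_rate = 0.0 if th <= TINY else sum(
            len(v) * (len(v) - 1) / 2.0 for v in demes.values()
        ) / th
        mig_rate = migration * k if n_pops > 1 else 0.0
        total = coal_rate + mig_rate
        if total <= 0:
            if t < tau:
                t = tau
                continue
            # theta0 ~ 0 and no migration needed: collapse everything at tau
            th = TINY
            coal_rate = sum(len(v) * (len(v) - 1) / 2.0 for v in demes.values()) / th
            if coal_rate <= 0:
                # lineages isolated in different demes with no migration
                raise RuntimeError("coalescent cannot complete: no events possible")
            total = coal_rate
        wait = rng.exponential(1.0 / total)
        if t < tau < t + wait:
            t = tau
            continue
        t += wait
        if rng.random() < mig_rate / total:
            idx = int(rng.integers(k))
            leaves, dm = lineages[idx]
            new_dm = int(rng.integers(n_pops - 1))
            if new_dm >= dm:
                new_dm += 1
            lineages[idx] = (leaves, new_dm)
            continue
        # coalescence: choose a deme weighted by its pair count, then a pair
        weights = np.array([len(v) * (len(v) - 1) / 2.0 for v in demes.values()])
        keys = list(demes)
        dm = keys[int(rng.choice(len(keys), p=weights / weights.sum()))]
        i, j = rng.choice(len(demes[dm]), size=2, replace=False)
        ia, ib = demes[dm][i], demes[dm][j]
        (la, _), (lb, _) = lineages[ia], lineages[ib]
        apply_mutations(la, t - born[ia])
        apply_mutations(lb, t - born[ib])
        merged = la + lb
        keep = [x for idx2, x in enumerate(lineages) if idx2 not in (ia, ib)]
        born = [b for idx2, b in enumerate(born) if idx2 not in (ia, ib)]
        lineages = keep + [(merged, dm)]
        born.append(t)

    unique: dict[int, str] = {}
    labels = []
    for g in genomes:
        if g not in unique:
            unique[g] = f"S{len(unique) + 1}"
        labels.append(unique[g])
    uniq_genomes = list(unique)
    m = np.zeros((len(uniq_genomes), len(uniq_genomes)), dtype=int)
    for i in range(len(uniq_genomes)):
        for j in range(i + 1, len(uniq_genomes)):
            m[i, j] = m[j, i] = (uniq_genomes[i] ^ uniq_genomes[j]).bit_count()
    dist = StepDistanceMatrix([unique[g] for g in uniq_genomes], m)
    return SimulatedSample(labels, deme_of, distances=dist)


def planted_partition_dataset(
    n_groups: int,
    pops_per_group: int = 4,
    n_per_pop: int = 8,
    within_rate: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[PopulationRecord], StepDistanceMatrix, list[list[str]]]:
    """Spatially clustered populations with strongly diverged group haplotypes.

    Each group occupies a distinct spatial cluster and is (nearly) fixed for
    a private haplotype; ``within_rate`` is the chance an individual carries
    a one-step private variant.  Used for SAMOVA recovery tests.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = [f"G{g}" for g in range(n_groups)] + [f"g{g}v" for g in range(n_groups)]
    m = np.zeros((2 * n_groups, 2 * n_groups), dtype=int)
    for i in range(2 * n_groups):
        for j in range(2 * n_groups):
            if i == j:
                continue
            gi, gj = i % n_groups, j % n_groups
            base = 0 if gi == gj else 10  # groups widely separated
            extra = (i >= n_groups) + (j >= n_groups)
            m[i, j] = base + extra if i != j else 0
    d = StepDistanceMatrix(labels, m)
    pops = []
    truth = []
    centers = [(90.0 + 5.0 * g, 30.0 + 4.0 * (g % 2)) for g in range(n_groups)]
    for g in range(n_groups):
        group_codes = []
        for p in range(pops_per_group):
            counts: dict[str, int] = {}
            for _ in range(n_per_pop):
                h = f"g{g}v" if rng.random() < within_rate else f"G{g}"
                counts[h] = counts.get(h, 0) + 1
            code = f"P{g}_{p}"
            group_codes.append(code)
            pops.append(
                PopulationRecord(
                    code=code,
                    location=f"cluster {g}",
                    lon=centers[g][0] + float(rng.normal(0, 0.4)),
                    lat=centers[g][1] + float(rng.normal(0, 0.4)),
                    altitude_m=4000.0,
                    n=n_per_pop,
                    counts=counts,
                )
            )
        truth.append(group_codes)
    return pops, d, truth
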