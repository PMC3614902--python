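"""Gene and nucleotide diversity, and population differentiation.

Implements Nei's unbiased gene diversity, nucleotide diversity from
haplotype step distances, and the Pons & Petit (1996) decomposition into
within- and total-population components for both unordered (frequency-only:
``H_S``, ``H_T``, ``G_ST``) and ordered (distance-weighted: ``V_S``,
``V_T``, ``N_ST``) alleles, with the haplotype-relabelling permutation test
that asks whether N_ST exceeds G_ST (the signature of phylogeographic
structure: closely related haplotypes co-occurring within populations).

Estimator conventions (PERMUT's):

* per-population unbiased diversity  h_k = n_k (1 - sum_i x_ik^2) / (n_k - 1)
* H_S = unweighted mean of h_k over populations
* H_T = 1 - sum_i xbar_i^2 + H_S / (n~ s),  xbar the unweighted mean
  frequency and n~ the harmonic mean sample size over the s populations
* V_S, V_T identical in form with 1{i != j} replaced by the distance pi_ij.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .haplotypes import StepDistanceMatrix

__all__ = [
    "PopulationRecord",
    "DiversityStats",
    "UndefinedDiversityError",
    "gene_diversity",
    "nucleotide_diversity",
    "permut_stats",
    "gst_nst_permutation_test",
]


class UndefinedDiversityError(ValueError):
    """Raised when a diversity or differentiation statistic is undefined."""


@dataclass
class PopulationRecord:
    """Per-population sample: location, size and haplotype counts."""

    code: str
    location: str
    lon: float
    lat: float
    altitude_m: float
    n: int
    counts: dict[str, int]
    h_printed: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"population {self.code}: n must be >= 1")
        if sum(self.counts.values()) != self.n:
            raise ValueError(f"population {self.code}: counts do not sum to n")
        if any(c < 1 for c in self.counts.values()):
            raise ValueError(f"population {self.code}: zero/negative count")

    @property
    def haplotypes(self) -> list[str]:
        return sorted(self.counts)


@dataclass
class DiversityStats:
    h_per_population: dict[str, float]
    h_species: float
    pi_species: float | None
    H_S: float
    H_T: float
    V_S: float
    V_T: float
    G_ST: float
    N_ST: float
    U: float | None = None
    p_value: float | None = None
    n_permutations: int | None = None


def _count_values(counts) -> np.ndarray:
    if isinstance(counts, Mapping):
        vals = np.asarray(list(counts.values()), dtype=float)
    else:
        vals = np.asarray(list(counts), dtype=float)
    if (vals < 0).any():
        raise ValueError("negative haplotype count")
    return vals


def gene_diversity(counts) -> float:
    """Nei's unbiased gene (haplotype) diversity.

    ``h = n (1 - sum p_i^2) / (n - 1)`` with ``p_i`` the observed haplotype
    frequencies.  Defined only for n >= 2.
    """
    vals = _count_values(counts)
    n = vals.sum()
    if n < 2:
        raise UndefinedDiversityError("gene diversity undefined for n < 2")
    p = vals / n
    return float(n * (1.0 - np.sum(p**2)) / (n - 1.0))


def nucleotide_diversity(
    counts: Mapping[str, int], d: StepDistanceMatrix, L: float
) -> float:
    """Nucleotide diversity: mean pairwise difference per site.

    ``pi = [n/(n-1)] sum_{i != j} p_i p_j d_ij / L`` over ordered haplotype
    pairs, with d_ij in mutational steps and L the sequence length.
    """
    if L <= 0:
        raise ValueError("sequence length must be positive")
    vals = np.asarray([counts[h] for h in counts], dtype=float)
    n = vals.sum()
    if n < 2:
        raise UndefinedDiversityError("nucleotide diversity undefined for n < 2")
    sub = d.submatrix(list(counts))
    p = vals / n
    return float(n / (n - 1.0) * (p @ sub.matrix @ p) / L)


def _frequency_table(
    pops: Sequence[PopulationRecord], labels: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    idx = {h: i for i, h in enumerate(labels)}
    X = np.zeros((len(pops), len(labels)))
    n = np.zeros(len(pops))
    for k, pop in enumerate(pops):
        n[k] = pop.n
        for h, c in pop.counts.items():
            X[k, idx[h]] = c / pop.n
    return X, n


def _pons_petit(
    X: np.ndarray, n: np.ndarray, D: np.ndarray
) -> tuple[float, float, float, float]:
    """Return (H_S, H_T, V_S, V_T) from frequencies X, sizes n, distances D."""
    s = len(n)
    nh = s / np.sum(1.0 / n)  # harmonic mean sample size
    corr = n / (n - 1.0)
    hS = corr * (1.0 - np.sum(X**2, axis=1))
    H_S = float(hS.mean())
    xbar = X.mean(axis=0)
    H_T = float(1.0 - np.sum(xbar**2) + H_S / (nh * s))
    vS = corr * np.einsum("ki,ij,kj->k", X, D, X)
    V_S = float(vS.mean())
    V_T = float(xbar @ D @ xbar + V_S / (nh * s))
    return H_S, H_T, V_S, V_T


def _validate(pops: Sequence[PopulationRecord], d: StepDistanceMatrix) -> None:
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    for pop in pops:
        if pop.n < 2:
            raise ValueError(f"population {pop.code}: n >= 2 required")
        missing = set(pop.counts) - set(d.labels)
        if missing:
            raise ValueError(f"population {pop.code}: unknown haplotypes {missing}")


def permut_stats(
    pops: Sequence[PopulationRecord],
    d: StepDistanceMatrix,
    L: float | None = None,
) -> DiversityStats:
    """Pons & Petit diversity decomposition over a set of populations.

    Computes per-population and species-level gene diversity, H_S/H_T/G_ST
    (unordered) and V_S/V_T/N_ST (ordered, weighted by the mutational-step
    distances in *d*).  Species-level h and pi use pooled counts.
    """
    _validate(pops, d)
    X, n = _frequency_table(pops, d.labels)
    H_S, H_T, V_S, V_T = _pons_petit(X, n, d.matrix.astype(float))
    if H_T <= 0:
        raise UndefinedDiversityError(
            "all populations fixed for the same haplotype: differentiation undefined"
        )
    pooled: dict[str, int] = {}
    for pop in pops:
        for h, c in pop.counts.items():
            pooled[h] = pooled.get(h, 0) + c
    return DiversityStats(
        h_per_population={p.code: gene_diversity(p.counts) for p in pops},
        h_species=gene_diversity(pooled),
        pi_species=None if L is None else nucleotide_diversity(pooled, d, L),
        H_S=H_S,
        H_T=H_T,
        V_S=V_S,
        V_T=V_T,
        G_ST=(H_T - H_S) / H_T,
        N_ST=(V_T - V_S) / V_T if V_T > 0 else float("nan"),
    )


def gst_nst_permutation_test(
    pops: Sequence[PopulationRecord],
    d: StepDistanceMatrix,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    L: float | None = None,
) -> DiversityStats:
    """Permutation U-test of N_ST against G_ST.

    Haplotype identities are permuted in the distance matrix (row/column
    relabelling), holding the frequency table fixed; G_ST is invariant under
    this scheme while N_ST is recomputed each time.  The one-sided p-value is
    the fraction of permutations with ``N_ST - G_ST`` at least the observed
    value (with the +1 inclusion of the identity), and U is the observed
    difference standardized by the permutation null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    stats = permut_stats(pops, d, L=L)
    X, n = _frequency_table(pops, d.labels)
    D = d.matrix.astype(float)
    observed = stats.N_ST - stats.G_ST
    diffs = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(d.labels))
        Dp = D[np.ix_(perm, perm)]
        _, _, V_S, V_T = _pons_petit(X, n, Dp)
        N_perm = (V_T - V_S) / V_T if V_T > 0 else np.nan
        diffs[b] = N_perm - stats.G_ST
    diffs = diffs[~np.isnan(diffs)]
    p = (1.0 + np.sum(diffs >= observed - 1e-12)) / (len(diffs) + 1.0)
    sd = diffs.std(ddof=1)
    stats.U = float((observed - diffs.mean()) / sd) if sd > 0 else 0.0
    stats.p_value = float(p)
    stats.n_permutations = int(n_perm)
    return stats
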