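"""Spatial population structure: AMOVA, SAMOVA, pairwise Phi_ST and Mantel.

AMOVA follows the Excoffier-Smouse-Quattro sums-of-squares decomposition of
squared inter-individual mutational-step distances into among-group,
among-population-within-group and within-population components, with the
corresponding Phi-statistics (F_CT, F_SC, F_ST) and permutation tests.
Because every individual carries exactly one haplotype, all sums of squares
reduce to quadratic forms in per-population haplotype count vectors, which
keeps the permutation and annealing loops cheap.

SAMOVA searches for the partition of populations into K geographically
contiguous groups maximizing F_CT by simulated annealing on a Delaunay
neighborhood graph built on locally projected coordinates.
"""

from __future__ import annotations

import math
import re
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .diversity import PopulationRecord
from .haplotypes import StepDistanceMatrix

__all__ = [
    "AmovaResult",
    "SamovaResult",
    "GeoMatrix",
    "parse_dms",
    "great_circle",
    "geo_matrix",
    "amova",
    "pairwise_phist",
    "samova",
    "mantel",
    "contiguity_graph",
]

EARTH_RADIUS_KM = 6371.0

_DMS = re.compile(r"(\d+(?:\.\d+)?)\s*°\s*(?:(\d+(?:\.\d+)?)\s*[′'])?")


def parse_dms(text: str):
    """Parse a degree-minute coordinate string to decimal degrees.

    Accepts a single coordinate (``"91°06′"``) or a longitude/latitude pair
    separated by ``/`` (``"91°06′/29°46′"``), returning a float or an
    (lon, lat) tuple respectively.  Hemisphere is assumed E/N.
    """
    if "/" in text:
        lon_s, lat_s = text.split("/", 1)
        return parse_dms(lon_s), parse_dms(lat_s)
    m = _DMS.search(text)
    if not m:
        raise ValueError(f"cannot parse coordinate {text!r}")
    deg = float(m.group(1))
    minutes = float(m.group(2)) if m.group(2) else 0.0
    return deg + minutes / 60.0


def great_circle(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine great-circle distance in km between (lon, lat) points."""
    lon1, lat1 = a
    lon2, lat2 = b
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude {lat} outside [-90, 90]")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlmb = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


@dataclass
class GeoMatrix:
    codes: list[str]
    km: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.km, dtype=float)
        if (m < 0).any() or (np.diag(m) != 0).any() or not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric, nonnegative, zero-diagonal")
        self.km = m


def geo_matrix(pops: Sequence[PopulationRecord]) -> GeoMatrix:
    """Pairwise great-circle distances between population locations."""
    n = len(pops)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = great_circle(
                (pops[i].lon, pops[i].lat), (pops[j].lon, pops[j].lat)
            )
    return GeoMatrix([p.code for p in pops], m)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


@dataclass
class AmovaResult:
    df: dict[str, int]
    sums_of_squares: dict[str, float]
    variance_components: dict[str, float]
    phi: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0
    negative_components: bool = False


def _counts_matrix(pops: Sequence[PopulationRecord], labels: Sequence[str]) -> np.ndarray:
    idx = {h: i for i, h in enumerate(labels)}
    C = np.zeros((len(pops), len(labels)))
    for k, pop in enumerate(pops):
        for h, c in pop.counts.items():
            C[k, idx[h]] = c
    return C


def _ss_within(C: np.ndarray, D2: np.ndarray) -> np.ndarray:
    """Per-population within sums of squares (1/(2 n_p)) sum_{i,j in p} d^2."""
    n = C.sum(axis=1)
    return np.einsum("ki,ij,kj->k", C, D2, C) / (2.0 * n)


def _one_level(C: np.ndarray, D2: np.ndarray):
    """Single-level AMOVA: among/within populations.  Returns Phi_ST pieces."""
    n = C.sum(axis=1)
    N = n.sum()
    P = len(n)
    ctot = C.sum(axis=0)
    ss_total = ctot @ D2 @ ctot / (2.0 * N)
    ss_w = _ss_within(C, D2).sum()
    ss_a = ss_total - ss_w
    sigma_w = ss_w / (N - P)
    n_c = (N - np.sum(n**2) / N) / (P - 1)
    sigma_a = (ss_a / (P - 1) - sigma_w) / n_c
    total = sigma_a + sigma_w
    phi = sigma_a / total if total != 0 else np.nan
    return ss_a, ss_w, sigma_a, sigma_w, phi


def _two_level(C: np.ndarray, D2: np.ndarray, groups: list[np.ndarray]):
    n = C.sum(axis=1)
    N = n.sum()
    P = len(n)
    G = len(groups)
    ctot = C.sum(axis=0)
    ss_total = ctot @ D2 @ ctot / (2.0 * N)
    ss_wp = _ss_within(C, D2).sum()
    ss_group_tot = 0.0
    sum_n2_over_Ng = 0.0
    sum_Ng2 = 0.0
    for g in groups:
        Cg = C[g].sum(axis=0)
        Ng = n[g].sum()
        ss_group_tot += Cg @ D2 @ Cg / (2.0 * Ng)
        sum_n2_over_Ng += np.sum(n[g] ** 2) / Ng
        sum_Ng2 += Ng**2
    ss_ap = ss_group_tot - ss_wp
    ss_ag = ss_total - ss_group_tot
    df_a, df_b, df_w = G - 1, P - G, N - P
    sigma_w = ss_wp / df_w
    if df_b > 0:
        n1 = (N - sum_n2_over_Ng) / df_b
        sigma_b = (ss_ap / df_b - sigma_w) / n1
    else:
        sigma_b = np.nan
    n2 = (sum_n2_over_Ng - np.sum(n**2) / N) / df_a
    n3 = (N - sum_Ng2 / N) / df_a
    sb = 0.0 if np.isnan(sigma_b) else sigma_b
    sigma_a = (ss_ag / df_a - sigma_w - n2 * sb) / n3
    total = sigma_a + sb + sigma_w
    f_ct = sigma_a / total if total != 0 else np.nan
    f_sc = sigma_b / (sb + sigma_w) if df_b > 0 and (sb + sigma_w) != 0 else np.nan
    f_st = (sigma_a + sb) / total if total != 0 else np.nan
    return {
        "df": {"among_groups": int(df_a), "among_pops_within_groups": int(df_b), "within_pops": int(df_w)},
        "ss": {"among_groups": float(ss_ag), "among_pops_within_groups": float(ss_ap), "within_pops": float(ss_wp)},
        "sigma": {"a": float(sigma_a), "b": float(sigma_b), "c": float(sigma_w)},
        "phi": {"F_CT": float(f_ct), "F_SC": float(f_sc), "F_ST": float(f_st)},
    }


def _individual_codes(pops: Sequence[PopulationRecord], labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Flat array of per-individual haplotype indices, and population sizes."""
    idx = {h: i for i, h in enumerate(labels)}
    codes = []
    sizes = []
    for pop in pops:
        for h in sorted(pop.counts):
            codes.extend([idx[h]] * pop.counts[h])
        sizes.append(pop.n)
    return np.asarray(codes), np.asarray(sizes)


def _counts_from_codes(codes: np.ndarray, sizes: np.ndarray, H: int) -> np.ndarray:
    C = np.zeros((len(sizes), H))
    start = 0
    for k, size in enumerate(sizes):
        C[k] = np.bincount(codes[start : start + size], minlength=H)
        start += size
    return C


def amova(
    pops: Sequence[PopulationRecord],
    d: StepDistanceMatrix,
    grouping: Sequence[Sequence[str]] | None = None,
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = None,
) -> AmovaResult:
    """Hierarchical analysis of molecular variance on step distances.

    With *grouping* (a partition of population codes) the analysis is
    two-level and F_CT/F_SC/F_ST are each tested with their own permutation
    scheme (populations among groups; individuals among populations within
    groups; individuals among populations).  Without a grouping a one-level
    AMOVA returns Phi_ST (= F_ST) with the individual-level permutation test.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = d.labels
    C = _counts_matrix(pops, labels)
    D2 = d.matrix.astype(float) ** 2
    codes, sizes = _individual_codes(pops, labels)
    H = len(labels)
    code_of = {p.code: k for k, p in enumerate(pops)}

    if grouping is None:
        ss_a, ss_w, sigma_a, sigma_w, phi = _one_level(C, D2)
        if sigma_a + sigma_w == 0:
            raise ValueError("total molecular variance is zero")
        count = 0
        for _ in range(max(n_perm, 0)):
            perm = rng.permutation(codes)
            Cp = _counts_from_codes(perm, sizes, H)
            phi_p = _one_level(Cp, D2)[4]
            if phi_p >= phi - 1e-12:
                count += 1
        res = AmovaResult(
            df={"among_pops": len(pops) - 1, "within_pops": int(sizes.sum()) - len(pops)},
            sums_of_squares={"among_pops": float(ss_a), "within_pops": float(ss_w)},
            variance_components={"a": float(sigma_a), "c": float(sigma_w)},
            phi={"F_ST": float(phi)},
            p_values={"F_ST": (count + 1.0) / (n_perm + 1.0)} if n_perm else {},
            n_permutations=n_perm,
            negative_components=bool(sigma_a < 0),
        )
        return res

    seen = [c for grp in grouping for c in grp]
    if sorted(seen) != sorted(code_of):
        raise ValueError("grouping must cover every population exactly once")
    groups = [np.asarray([code_of[c] for c in grp]) for grp in grouping]
    out = _two_level(C, D2, groups)
    if sum(v for v in out["sigma"].values() if not np.isnan(v)) == 0:
        raise ValueError("total molecular variance is zero")
    group_sizes = [len(g) for g in groups]
    pvals: dict[str, float] = {}
    if n_perm:
        obs = out["phi"]
        counts = {"F_CT": 0, "F_SC": 0, "F_ST": 0}
        # F_CT: permute populations among groups
        for _ in range(n_perm):
            perm_pops = rng.permutation(len(pops))
            gp, start = [], 0
            for gs in group_sizes:
                gp.append(perm_pops[start : start + gs])
                start += gs
            val = _two_level(C, D2, gp)["phi"]["F_CT"]
            if val >= obs["F_CT"] - 1e-12:
                counts["F_CT"] += 1
        # F_SC: permute individuals among populations within groups
        starts = np.concatenate([[0], np.cumsum(sizes)])
        for _ in range(n_perm):
            perm = codes.copy()
            for g in groups:
                sel = np.concatenate([np.arange(starts[k], starts[k + 1]) for k in g])
                perm[sel] = rng.permutation(perm[sel])
            Cp = _counts_from_codes(perm, sizes, H)
            val = _two_level(Cp, D2, groups)["phi"]["F_SC"]
            if not np.isnan(val) and val >= obs["F_SC"] - 1e-12:
                counts["F_SC"] += 1
        # F_ST: permute individuals among populations
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            Cp = _counts_from_codes(perm, sizes, H)
            val = _two_level(Cp, D2, groups)["phi"]["F_ST"]
            if val >= obs["F_ST"] - 1e-12:
                counts["F_ST"] += 1
        pvals = {k: (v + 1.0) / (n_perm + 1.0) for k, v in counts.items()}
        if np.isnan(out["phi"]["F_SC"]):
            pvals.pop("F_SC", None)
    return AmovaResult(
        df=out["df"],
        sums_of_squares=out["ss"],
        variance_components=out["sigma"],
        phi=out["phi"],
        p_values=pvals,
        n_permutations=n_perm,
        negative_components=bool(
            any(v < 0 for v in out["sigma"].values() if not np.isnan(v))
        ),
    )


def pairwise_phist(
    pops: Sequence[PopulationRecord],
    d: StepDistanceMatrix,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Pairwise Phi_ST between populations with permutation p-values.

    Each pair is a two-population one-level AMOVA; individuals are permuted
    between the two populations (vectorized over permutations).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = d.labels
    H = len(labels)
    D2 = d.matrix.astype(float) ** 2
    P = len(pops)
    phi_m = np.zeros((P, P))
    p_m = np.ones((P, P))
    idx = {h: i for i, h in enumerate(labels)}

    def pop_codes(pop: PopulationRecord) -> np.ndarray:
        out = []
        for h in sorted(pop.counts):
            out.extend([idx[h]] * pop.counts[h])
        return np.asarray(out)

    code_arrays = [pop_codes(p) for p in pops]
    for i in range(P):
        for j in range(i + 1, P):
            codes = np.concatenate([code_arrays[i], code_arrays[j]])
            sizes = np.asarray([pops[i].n, pops[j].n])
            C = _counts_from_codes(codes, sizes, H)
            try:
                phi = _one_level(C, D2)[4]
            except ZeroDivisionError:  # pragma: no cover
                phi = np.nan
            phi_m[i, j] = phi_m[j, i] = phi
            if n_perm and np.isfinite(phi):
                mat = np.tile(codes, (n_perm, 1))
                mat = rng.permuted(mat, axis=1)
                C1 = np.stack([(mat[:, : sizes[0]] == h).sum(axis=1) for h in range(H)], axis=1).astype(float)
                C2 = np.stack([(mat[:, sizes[0] :] == h).sum(axis=1) for h in range(H)], axis=1).astype(float)
                phis = _phi_two_pop_batch(C1, C2, D2)
                count = np.sum(phis >= phi - 1e-12)
                p_m[i, j] = p_m[j, i] = (count + 1.0) / (n_perm + 1.0)
    return [p.code for p in pops], phi_m, p_m


def _phi_two_pop_batch(C1: np.ndarray, C2: np.ndarray, D2: np.ndarray) -> np.ndarray:
    """Vectorized one-level Phi_ST for B two-population count matrices."""
    n1 = C1.sum(axis=1)
    n2 = C2.sum(axis=1)
    N = n1 + n2
    ct = C1 + C2
    ss_total = np.einsum("bi,ij,bj->b", ct, D2, ct) / (2.0 * N)
    ss_w = (
        np.einsum("bi,ij,bj->b", C1, D2, C1) / (2.0 * n1)
        + np.einsum("bi,ij,bj->b", C2, D2, C2) / (2.0 * n2)
    )
    ss_a = ss_total - ss_w
    sigma_w = ss_w / (N - 2)
    n_c = (N - (n1**2 + n2**2) / N) / 1.0
    sigma_a = (ss_a - sigma_w) / n_c
    total = sigma_a + sigma_w
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total != 0, sigma_a / total, np.nan)


# ---------------------------------------------------------------------------
# SAMOVA
# ---------------------------------------------------------------------------


@dataclass
class SamovaResult:
    K: int
    grouping: list[list[str]]
    F_CT: float
    fct_per_repetition: list[float]
    repetitions: int


def _project_aeqd(lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
    """Azimuthal equidistant projection centered on the coordinate centroid."""
    lon0, lat0 = float(np.mean(lons)), float(np.mean(lats))
    xy = np.zeros((len(lons), 2))
    phi0 = math.radians(lat0)
    for i, (lon, lat) in enumerate(zip(lons, lats)):
        c = great_circle((lon0, lat0), (lon, lat))
        phi = math.radians(lat)
        dl = math.radians(lon - lon0)
        y_ = math.cos(phi0) * math.sin(phi) - math.sin(phi0) * math.cos(phi) * math.cos(dl)
        x_ = math.sin(dl) * math.cos(phi)
        az = math.atan2(x_, y_)
        xy[i] = (c * math.sin(az), c * math.cos(az))
    return xy


def contiguity_graph(lons: Sequence[float], lats: Sequence[float]) -> list[set[int]]:
    """Delaunay neighborhood graph on AEQD-projected coordinates.

    Falls back to a 3-nearest-neighbor graph for degenerate (e.g. collinear)
    configurations that Delaunay triangulation cannot handle.
    """
    xy = _project_aeqd(np.asarray(lons, dtype=float), np.asarray(lats, dtype=float))
    n = len(xy)
    adj: list[set[int]] = [set() for _ in range(n)]
    try:
        tri = Delaunay(xy)
        for simplex in tri.simplices:
            for a in simplex:
                for b in simplex:
                    if a != b:
                        adj[a].add(int(b))
    except (QhullError, ValueError):
        dmat = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
        np.fill_diagonal(dmat, np.inf)
        k = min(3, n - 1)
        for i in range(n):
            for j in np.argsort(dmat[i])[:k]:
                adj[i].add(int(j))
                adj[int(j)].add(i)
    return adj


def _connected_without(adj: list[set[int]], members: set[int], removed: int) -> bool:
    rest = members - {removed}
    if not rest:
        return False
    start = next(iter(rest))
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v in rest and v not in seen:
                seen.add(v)
                stack.append(v)
    return seen == rest


def samova(
    pops: Sequence[PopulationRecord],
    d: StepDistanceMatrix,
    K: int,
    n_repetitions: int = 100,
    n_steps: int = 10000,
    seed: int | np.random.Generator | None = None,
    cooling: float = 0.9,
) -> SamovaResult:
    """Search for the K-group geographically contiguous partition maximizing F_CT.

    Simulated annealing: the initial temperature is set from probe proposals
    so that roughly 80% of early downhill moves are accepted, cooled
    geometrically (x ``cooling`` in 100 stages); a proposal moves one
    boundary population into a Delaunay-neighboring group, keeping every
    group non-empty and connected.  The best configuration over
    ``n_repetitions`` independent repetitions is retained.
    """
    P = len(pops)
    if not 2 <= K <= P:
        raise ValueError(f"K={K} outside [2, {P}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    C = _counts_matrix(pops, d.labels)
    D2 = d.matrix.astype(float) ** 2
    n = C.sum(axis=1)
    adj = contiguity_graph([p.lon for p in pops], [p.lat for p in pops])

    def fct(assign: np.ndarray) -> float:
        groups = [np.flatnonzero(assign == g) for g in range(K)]
        return _two_level(C, D2, groups)["phi"]["F_CT"]

    if K == P:
        assign = np.arange(P)
        value = fct(assign)
        return SamovaResult(K, [[pops[i].code] for i in range(P)], float(value), [float(value)], 1)

    def grow_partition() -> np.ndarray:
        assign = np.full(P, -1)
        seeds = rng.choice(P, size=K, replace=False)
        for g, s in enumerate(seeds):
            assign[s] = g
        remaining = P - K
        while remaining:
            order = rng.permutation(K)
            grew = False
            for g in order:
                cand = [
                    v
                    for u in np.flatnonzero(assign == g)
                    for v in adj[u]
                    if assign[v] == -1
                ]
                if cand:
                    v = int(rng.choice(cand))
                    assign[v] = g
                    remaining -= 1
                    grew = True
                    if not remaining:
                        break
            if not grew:  # disconnected graph; assign leftovers at random
                for v in np.flatnonzero(assign == -1):
                    assign[v] = int(rng.integers(K))
                remaining = 0
        return assign

    def propose(assign: np.ndarray):
        for _ in range(50):
            p = int(rng.integers(P))
            g = assign[p]
            targets = {assign[v] for v in adj[p]} - {g}
            if not targets:
                continue
            members = set(np.flatnonzero(assign == g).tolist())
            if len(members) == 1 or not _connected_without(adj, members, p):
                continue
            return p, int(rng.choice(sorted(targets)))
        return None

    best_val = -np.inf
    best_assign = None
    per_rep: list[float] = []
    stage = max(1, n_steps // 100)
    for _rep in range(n_repetitions):
        assign = grow_partition()
        cur = fct(assign)
        # probe for initial temperature (~80% acceptance of typical moves)
        deltas = []
        for _ in range(25):
            mv = propose(assign)
            if mv is None:
                break
            p, g2 = mv
            old = assign[p]
            assign[p] = g2
            deltas.append(abs(fct(assign) - cur))
            assign[p] = old
        t = (np.mean(deltas) / math.log(1 / 0.8)) if deltas else 1e-3
        t = max(t, 1e-9)
        rep_best, rep_best_assign = cur, assign.copy()
        for step in range(n_steps):
            mv = propose(assign)
            if mv is None:
                break
            p, g2 = mv
            old = assign[p]
            assign[p] = g2
            new = fct(assign)
            delta = new - cur
            if delta >= 0 or rng.random() < math.exp(delta / t):
                cur = new
                if cur > rep_best:
                    rep_best, rep_best_assign = cur, assign.copy()
            else:
                assign[p] = old
            if (step + 1) % stage == 0:
                t = max(t * cooling, 1e-12)
        per_rep.append(float(rep_best))
        if rep_best > best_val:
            best_val, best_assign = rep_best, rep_best_assign
    grouping = [
        [pops[i].code for i in np.flatnonzero(best_assign == g)] for g in range(K)
    ]
    grouping = [g for g in grouping if g]
    return SamovaResult(K, grouping, float(best_val), per_rep, n_repetitions)


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------


def mantel(
    m1: np.ndarray,
    m2: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Mantel test: Pearson correlation of two distance matrices.

    The correlation is computed over lower-triangle entries; significance by
    simultaneous row/column permutation of the second matrix.  ``alternative``
    is ``"two-sided"`` (default) or ``"greater"``.
    """
    a = np.asarray(m1, dtype=float)
    b = np.asarray(m2, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    il = np.tril_indices(a.shape[0], k=-1)
    x = a[il]
    if x.std() == 0:
        raise ValueError("first matrix is constant: correlation undefined")
    if b[il].std() == 0:
        raise ValueError("second matrix is constant: correlation undefined")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def corr(mat: np.ndarray) -> float:
        y = mat[il]
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(b)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(a.shape[0])
        r_p = corr(b[np.ix_(perm, perm)])
        if alternative == "greater":
            hit = r_p >= r_obs - 1e-12
        else:
            hit = abs(r_p) >= abs(r_obs) - 1e-12
        count += bool(hit)
    p = (count + 1.0) / (n_perm + 1.0)
    return r_obs, float(p)
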