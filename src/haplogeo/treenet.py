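"""Haplotype trees, statistical-parsimony networks and strict-clock dating.

Tree building is neighbor-joining (via Biopython's distance-tree
constructor) on Kimura two-parameter or mutational-step distances, with
midpoint rooting and character-resampling bootstrap.  The haplotype network
follows the statistical-parsimony construction: haplotypes are linked in
increasing step order up to the number of steps that still has >= 95%
probability of being free of homoplasy, with inferred intermediate nodes so
that every edge is a single mutational step.

The parsimony-connection probability is computed from an explicit
finite-sites model: mutations hit the L sites of the sequence uniformly at
random and a 4-state site revisited by a mutation reverts with probability
1/3.  The number of unobserved mutations M behind j observable differences
gets a geometric prior with mean j (the neutral pairwise-mutation-count
distribution, moment-matched to the data), and the connection at j steps is
"parsimonious" when the posterior probability of M = j exceeds the limit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np
from Bio.Phylo.BaseTree import Tree
from Bio.Phylo.TreeConstruction import DistanceMatrix as _BioDM
from Bio.Phylo.TreeConstruction import DistanceTreeConstructor

from .haplotypes import HaplotypeMatrix, StepDistanceMatrix, pairwise_steps

__all__ = [
    "DatingResult",
    "SaturationError",
    "k2p",
    "nj_tree",
    "midpoint_root",
    "bipartitions",
    "nj_bootstrap",
    "parsimony_limit",
    "parsimony_probability",
    "tcs_network",
    "strict_clock_age",
]

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
BASES = frozenset("ACGT")


class SaturationError(ValueError):
    """K2P distance undefined: substitution saturation (log argument <= 0)."""


def k2p(seq1: str, seq2: str) -> float:
    """Kimura two-parameter distance between two aligned sequences.

    ``d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)`` with P and Q the transition
    and transversion proportions over sites where both sequences carry an
    unambiguous base (gap or N columns are excluded pairwise).
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must have equal length")
    n = ts = tv = 0
    for a, b in zip(seq1.upper(), seq2.upper()):
        if a not in BASES or b not in BASES:
            continue
        n += 1
        if a != b:
            if (a, b) in TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise ValueError("no comparable sites")
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError("substitution saturation: K2P undefined")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def _as_bio_dm(labels: list[str], matrix: np.ndarray) -> _BioDM:
    lower = [[float(matrix[i, j]) for j in range(i + 1)] for i in range(len(labels))]
    return _BioDM(names=list(labels), matrix=lower)


def _fix_negative_lengths(tree: Tree) -> None:
    """Zero out negative NJ branch lengths, moving the deficit to the sibling
    so that leaf-to-leaf path lengths through the parent are preserved."""
    for clade in tree.find_clades(order="level"):
        kids = clade.clades
        if len(kids) < 2:
            continue
        for child in kids:
            bl = child.branch_length or 0.0
            if bl < 0:
                child.branch_length = 0.0
                for sib in kids:
                    if sib is not child:
                        sib.branch_length = (sib.branch_length or 0.0) + bl
                        break
    for clade in tree.find_clades():
        if clade.branch_length is not None and clade.branch_length < 0:
            clade.branch_length = 0.0


def nj_tree(d: StepDistanceMatrix | tuple[list[str], np.ndarray]) -> Tree:
    """Neighbor-joining (Saitou-Nei) tree from a distance matrix.

    Returns an unrooted tree (arbitrarily rooted representation); negative
    branch lengths are adjusted to zero with the deficit moved to the
    sibling branch.
    """
    labels, matrix = (d.labels, d.matrix) if isinstance(d, StepDistanceMatrix) else d
    if len(labels) < 3:
        raise ValueError("neighbor-joining requires at least three taxa")
    tree = DistanceTreeConstructor().nj(_as_bio_dm(list(labels), np.asarray(matrix, dtype=float)))
    _fix_negative_lengths(tree)
    for clade in tree.get_nonterminals():
        clade.name = None  # drop constructor's Inner# labels
    tree.rooted = False
    return tree


def midpoint_root(tree: Tree) -> Tree:
    """Root the tree at the midpoint of the longest leaf-to-leaf path."""
    tree.root_at_midpoint()
    tree.rooted = True
    return tree


def bipartitions(tree: Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions, each canonicalized to the side not containing
    the lexicographically first terminal."""
    terminals = sorted(t.name for t in tree.get_terminals())
    ref = terminals[0]
    full = set(terminals)
    out = set()
    for clade in tree.get_nonterminals():
        side = frozenset(t.name for t in clade.get_terminals())
        if ref in side:
            side = frozenset(full - side)
        if 0 < len(side) < len(full):
            out.add(side)
    return out


def nj_bootstrap(
    hm: HaplotypeMatrix,
    n_reps: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[Tree, dict[frozenset[str], float]]:
    """Bootstrap support for the NJ tree by resampling characters.

    Characters of the haplotype matrix are resampled with replacement,
    step distances and the NJ tree recomputed, and bipartition frequencies
    mapped back onto the original tree (stored as clade ``confidence``).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S = np.asarray([list(row) for row in hm.states], dtype=object)
    n_chars = S.shape[1]

    def steps_from(cols: np.ndarray) -> np.ndarray:
        sub = S[:, cols]
        n = len(hm.labels)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = np.sum(sub[i] != sub[j])
        return m

    base = nj_tree((list(hm.labels), steps_from(np.arange(n_chars))))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(base)}
    for _ in range(n_reps):
        cols = rng.integers(0, n_chars, size=n_chars)
        rep = nj_tree((list(hm.labels), steps_from(cols)))
        found = bipartitions(rep)
        for bp in counts:
            if bp in found:
                counts[bp] += 1
    support = {bp: c / n_reps for bp, c in counts.items()}
    terminals = sorted(t.name for t in base.get_terminals())
    ref, full = terminals[0], set(terminals)
    for clade in base.get_nonterminals():
        side = frozenset(t.name for t in clade.get_terminals())
        if ref in side:
            side = frozenset(full - side)
        if side in support:
            clade.confidence = 100.0 * support[side]
    return base, support


# ---------------------------------------------------------------------------
# statistical parsimony
# ---------------------------------------------------------------------------


@lru_cache(maxsize=32)
def _walk_distribution(L: int, max_mutations: int) -> np.ndarray:
    """P(end with j observable differences | M mutations) for all j, M.

    Random walk over site states: a mutation hits a fresh site (becomes a
    visible difference), a currently-differing site (reverts with prob 1/3,
    else stays different), or a previously-hit-but-identical site (becomes
    different again).  Returns array ``P[j, M]``.
    """
    M = max_mutations
    F = np.zeros((M + 2, M + 2))  # F[j, s]
    F[0, 0] = 1.0
    out = np.zeros((M + 1, M + 1))
    out[0, 0] = 1.0
    J = np.arange(M + 2, dtype=float)[:, None]
    S = np.arange(M + 2, dtype=float)[None, :]
    fresh = np.clip((L - J - S) / L, 0.0, 1.0)
    hit_diff = J / L
    hit_same = S / L
    # renormalize rows where j+s > L cannot occur (mass there is zero anyway)
    for m in range(1, M + 1):
        new = np.zeros_like(F)
        new[1:, :] += (F * fresh)[:-1, :]
        new[:-1, 1:] += (F * hit_diff / 3.0)[1:, :-1]
        new += F * hit_diff * (2.0 / 3.0)
        new[1:, :-1] += (F * hit_same)[:-1, 1:]
        F = new
        out[:, m] = F.sum(axis=1)[: M + 1]
    return out


def parsimony_probability(j: int, L: int, max_mutations: int = 320) -> float:
    """Posterior probability that j observable differences arose from exactly
    j mutations (i.e. the j-step connection is parsimonious)."""
    if j < 1:
        return 1.0
    if L < 1:
        raise ValueError("sequence length must be >= 1")
    M = min(max_mutations, max(60, 8 * j + 60))
    walk = _walk_distribution(int(L), M)
    if j > M:
        return 0.0
    b = j / (j + 1.0)  # geometric prior with mean j
    weights = b ** np.arange(M + 1)
    post = weights * walk[j, :]
    total = post.sum()
    if total <= 0:
        return 0.0
    return float(post[j] / total)


def parsimony_limit(L: int, p: float = 0.95) -> int:
    """Largest number of steps whose connection probability exceeds *p*.

    Single-step connections are always accepted, so the limit is at least 1.
    """
    if L < 1:
        raise ValueError("sequence length must be >= 1")
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    j = 1
    while j < L and parsimony_probability(j + 1, L) > p:
        j += 1
    return j


def tcs_network(
    hm: HaplotypeMatrix,
    freqs: dict[str, int] | None = None,
    p: float = 0.95,
    seq_length: int = 2106,
    limit: int | None = None,
) -> nx.Graph:
    """Statistical-parsimony haplotype network.

    Haplotype pairs are processed in increasing step order up to the
    connection *limit*: pairs one step apart are joined directly; more
    distant pairs are joined only when they bridge separate components,
    inserting inferred intermediate nodes so that every edge spans exactly
    one mutational step.  Ties break toward higher combined frequency, then
    lexicographic labels.  Disconnected components at the limit are returned
    with a warning.
    """
    d = pairwise_steps(hm)
    if limit is None:
        limit = parsimony_limit(seq_length, p)
    freqs = freqs or {}
    g = nx.Graph(connection_limit=int(limit), probability=p)
    for label in hm.labels:
        g.add_node(label, inferred=False, frequency=int(freqs.get(label, 1)))
    pairs = []
    for i, a in enumerate(hm.labels):
        for b in hm.labels[i + 1 :]:
            steps = d[a, b]
            if steps <= limit:
                fa, fb = freqs.get(a, 1), freqs.get(b, 1)
                pairs.append((steps, -(fa + fb), a, b))
    pairs.sort()
    counter = 0
    for steps, _negf, a, b in pairs:
        if steps == 1:
            g.add_edge(a, b, steps=1)
        elif not nx.has_path(g, a, b):
            prev = a
            for _ in range(steps - 1):
                counter += 1
                node = f"x{counter}"
                g.add_node(node, inferred=True, frequency=0)
                g.add_edge(prev, node, steps=1)
                prev = node
            g.add_edge(prev, b, steps=1)
    observed = [n for n, data in g.nodes(data=True) if not data["inferred"]]
    comp = {n: i for i, c in enumerate(nx.connected_components(g)) for n in c}
    if len({comp[n] for n in observed}) > 1:
        warnings.warn(
            "network disconnected at the connection limit; returning components",
            stacklevel=2,
        )
    return g


# ---------------------------------------------------------------------------
# strict-clock dating
# ---------------------------------------------------------------------------


@dataclass
class DatingResult:
    group1: list[str]
    group2: list[str]
    age_myr: float
    interval_myr: tuple[float, float]
    mu: float
    L: float
    method: str = "strict-clock distance"


def strict_clock_age(
    group1: list[str],
    group2: list[str],
    hm: HaplotypeMatrix,
    mu: float,
    L: float,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> DatingResult:
    """Strict-clock age of the split between two haplotype groups.

    The point estimate is the mean between-group mutational-step distance
    divided by ``2 mu L`` (years, reported in Myr).  The interval is a
    percentile parametric bootstrap over characters in which each observed
    character's multiplicity is resampled as Poisson(1): under the clock
    every character is one mutation event and the number of events on a
    branch is Poisson, so this reproduces the mutational variance of the
    between-group distance (a plain k-of-k resample would hold the total
    mutation count fixed and understate it).
    """
    s1, s2 = set(group1), set(group2)
    if not s1 or not s2 or s1 & s2:
        raise ValueError("groups must be disjoint and non-empty")
    if mu <= 0 or L <= 0:
        raise ValueError("mu and L must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = {lab: np.asarray(list(row), dtype=object) for lab, row in zip(hm.labels, hm.states)}
    missing = (s1 | s2) - set(rows)
    if missing:
        raise ValueError(f"unknown haplotypes {missing}")
    # per-character mean between-group difference
    contrib = np.zeros(hm.n_characters)
    pairs = [(a, b) for a in sorted(s1) for b in sorted(s2)]
    for a, b in pairs:
        contrib += (rows[a] != rows[b]).astype(float)
    contrib /= len(pairs)
    mean_steps = contrib.sum()
    scale = 1.0 / (2.0 * mu * L) / 1e6  # steps -> Myr
    age = mean_steps * scale
    if mean_steps == 0:
        warnings.warn("zero between-group distance: age is 0", stacklevel=2)
        return DatingResult(sorted(s1), sorted(s2), 0.0, (0.0, 0.0), mu, L)
    boots = np.empty(n_boot)
    k = len(contrib)
    for b_i in range(n_boot):
        mult = rng.poisson(1.0, size=k)
        boots[b_i] = float(mult @ contrib) * scale
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return DatingResult(sorted(s1), sorted(s2), float(age), (float(lo), float(hi)), mu, L)
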