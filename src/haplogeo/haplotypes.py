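"""Haplotype calling from aligned chloroplast sequences.

Variable sites are derived from a pre-aligned multi-locus alignment.
Nucleotide substitutions are single-column characters; insertions/deletions
are coded with *simple indel coding*: a maximal contiguous gap run with
identical start and end across sequences is one binary character (one
mutational event), gap runs with different or partially overlapping spans
are distinct characters.  Haplotypes are the distinct joint states over the
variable sites, and mutational-step distances count differing characters,
each substitution or indel contributing one step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AlignedSequences",
    "VariableSite",
    "HaplotypeMatrix",
    "StepDistanceMatrix",
    "AlignmentError",
    "AmbiguousBaseError",
    "scan_variable_sites",
    "call_haplotypes",
    "pairwise_steps",
]

GAP = "-"
VALID_CHARS = frozenset("ACGTN-")


class AlignmentError(ValueError):
    """Raised for malformed alignments (unequal lengths, empty input)."""


class AmbiguousBaseError(ValueError):
    """Raised when an ambiguous base (N) occurs at a variable site."""


@dataclass
class AlignedSequences:
    """A multi-locus alignment over a common set of individuals.

    Parameters
    ----------
    names
        Individual (sequence) identifiers, shared across loci.
    loci
        Mapping locus name -> list of aligned sequences, parallel to
        ``names``.  All sequences within a locus must have equal length.
    order
        Concatenation order of the loci.
    """

    names: list[str]
    loci: dict[str, list[str]]
    order: list[str]

    def __post_init__(self) -> None:
        if not self.names:
            raise AlignmentError("alignment contains no sequences")
        if len(set(self.names)) != len(self.names):
            raise AlignmentError("duplicate sequence names")
        if set(self.order) != set(self.loci):
            raise AlignmentError("locus order does not match locus table")
        for locus in self.order:
            seqs = self.loci[locus]
            if len(seqs) != len(self.names):
                raise AlignmentError(
                    f"locus {locus!r}: {len(seqs)} sequences for "
                    f"{len(self.names)} individuals"
                )
            lengths = {len(s) for s in seqs}
            if len(lengths) != 1:
                raise AlignmentError(f"locus {locus!r}: unequal sequence lengths")
            bad = set("".join(seqs).upper()) - VALID_CHARS
            if bad:
                raise AlignmentError(f"locus {locus!r}: invalid characters {bad}")

    @property
    def locus_lengths(self) -> dict[str, int]:
        return {locus: len(self.loci[locus][0]) for locus in self.order}

    @property
    def total_length(self) -> int:
        return sum(self.locus_lengths.values())

    def concatenated(self, name: str) -> str:
        i = self.names.index(name)
        return "".join(self.loci[locus][i] for locus in self.order)


@dataclass(frozen=True)
class VariableSite:
    """One coded character of the alignment.

    ``position`` and ``end`` are 1-based inclusive column coordinates within
    ``locus``; substitutions have ``position == end`` while indel characters
    span the shared gap run.
    """

    locus: str
    position: int
    end: int
    kind: str  # "substitution" | "indel"
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "indel"):
            raise ValueError(f"unknown site kind {self.kind!r}")
        if self.kind == "substitution" and self.position != self.end:
            raise ValueError("substitution sites span a single column")


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal runs of '-' in *seq* as 0-based [start, end] inclusive."""
    runs = []
    start = None
    for i, c in enumerate(seq):
        if c == GAP:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(seq) - 1))
    return runs


def scan_variable_sites(alignment: AlignedSequences) -> list[VariableSite]:
    """Identify substitution columns and indel characters.

    Returns the sites ordered by locus (concatenation order) then by start
    position.  A contiguous gap run shared (with identical boundaries) by a
    subset of sequences yields exactly one indel character; columns with two
    or more distinct non-gap bases yield substitution characters.

    Raises
    ------
    AlignmentError
        If the alignment has fewer than two sequences.
    """
    if len(alignment.names) < 2:
        raise AlignmentError("need at least two sequences to scan for variation")
    sites: list[VariableSite] = []
    for locus in alignment.order:
        seqs = [s.upper() for s in alignment.loci[locus]]
        # indel characters: distinct maximal gap spans
        spans = sorted({run for s in seqs for run in _gap_runs(s)})
        for a, b in spans:
            states = set()
            for s in seqs:
                states.add(_indel_state(s, a, b))
            if len(states) >= 2:
                sites.append(
                    VariableSite(locus, a + 1, b + 1, "indel", tuple(sorted(states)))
                )
        # substitution columns: >=2 distinct non-gap bases
        for col in range(len(seqs[0])):
            bases = {s[col] for s in seqs} - {GAP}
            if len(bases - {"N"}) >= 2:
                sites.append(
                    VariableSite(
                        locus, col + 1, col + 1, "substitution", tuple(sorted(bases))
                    )
                )
    locus_rank = {locus: i for i, locus in enumerate(alignment.order)}
    sites.sort(key=lambda s: (locus_rank[s.locus], s.position, s.end))
    return sites


def _indel_state(seq: str, a: int, b: int) -> str:
    """State of *seq* for the indel character spanning 0-based [a, b]."""
    segment = seq[a : b + 1]
    runs = _gap_runs(seq)
    if (a, b) in runs:
        return GAP
    # no exact-match run: the (possibly partially gapped) segment is the state
    return segment


@dataclass
class HaplotypeMatrix:
    """Haplotype labels x character states, with optional individual assignments."""

    labels: list[str]
    states: list[tuple[str, ...]]
    sites: list[VariableSite] | None = None
    assignments: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.states):
            raise ValueError("labels and state rows differ in number")
        widths = {len(row) for row in self.states}
        if len(widths) > 1:
            raise ValueError("state rows have unequal width")
        if len(set(self.states)) != len(self.states):
            raise ValueError("haplotype rows are not distinct")

    @property
    def n_characters(self) -> int:
        return len(self.states[0]) if self.states else 0

    def row(self, label: str) -> tuple[str, ...]:
        return self.states[self.labels.index(label)]

    def restrict(self, kinds: set[str]) -> "HaplotypeMatrix":
        """Project onto characters whose site kind is in *kinds*, merging rows.

        Merged rows keep the first label in the current row order; this is a
        quotient of the full matrix (rows may merge, never split).
        """
        if self.sites is None:
            raise ValueError("site metadata required to restrict by kind")
        keep = [i for i, s in enumerate(self.sites) if s.kind in kinds]
        seen: dict[tuple[str, ...], str] = {}
        labels, states = [], []
        merged_assign: dict[str, list[str]] = {}
        for label, row in zip(self.labels, self.states):
            sub = tuple(row[i] for i in keep)
            if sub not in seen:
                seen[sub] = label
                labels.append(label)
                states.append(sub)
                merged_assign[label] = list(self.assignments.get(label, []))
            else:
                merged_assign[seen[sub]].extend(self.assignments.get(label, []))
        return HaplotypeMatrix(
            labels,
            states,
            [self.sites[i] for i in keep],
            merged_assign,
        )


@dataclass
class StepDistanceMatrix:
    """Symmetric matrix of mutational steps between haplotypes."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if (m < 0).any() or (np.diag(m) != 0).any() or not (m == m.T).all():
            raise ValueError("matrix must be symmetric, nonnegative, zero-diagonal")
        self.matrix = m

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def __getitem__(self, pair: tuple[str, str]) -> int:
        a, b = pair
        return int(self.matrix[self.index(a), self.index(b)])

    def submatrix(self, labels: list[str]) -> "StepDistanceMatrix":
        idx = [self.index(x) for x in labels]
        return StepDistanceMatrix(list(labels), self.matrix[np.ix_(idx, idx)])


def call_haplotypes(
    alignment: AlignedSequences,
    sites: list[VariableSite],
    mode: str = "with_indels",
    on_ambiguous: str = "error",
    canonical: HaplotypeMatrix | None = None,
) -> HaplotypeMatrix:
    """Assign each individual to a haplotype from its states at the variable sites.

    Parameters
    ----------
    mode
        ``"with_indels"`` uses every character; ``"substitutions_only"``
        restricts to substitution columns (a quotient: haplotypes can merge
        but never split).
    on_ambiguous
        ``"error"`` (default) raises on an N at a variable site;
        ``"drop"`` silently removes the individual.
    canonical
        Optional reference matrix; state vectors matching one of its rows take
        the canonical label, novel haplotypes get ``"Hn"`` labels in
        first-occurrence order.
    """
    if mode not in ("with_indels", "substitutions_only"):
        raise ValueError(f"unknown mode {mode!r}")
    used = [s for s in sites if mode == "with_indels" or s.kind == "substitution"]
    state_of: dict[str, tuple[str, ...]] = {}
    for i, name in enumerate(alignment.names):
        row = []
        ambiguous = False
        for s in used:
            seq = alignment.loci[s.locus][i].upper()
            if s.kind == "substitution":
                st = seq[s.position - 1]
                if st == "N":
                    ambiguous = True
            else:
                st = _indel_state(seq, s.position - 1, s.end - 1)
                if "N" in st:
                    ambiguous = True
            row.append(st)
        if ambiguous:
            if on_ambiguous == "drop":
                continue
            raise AmbiguousBaseError(f"ambiguous base in {name!r} at a variable site")
        state_of[name] = tuple(row)

    canon = {}
    if canonical is not None:
        canon = {row: lab for lab, row in zip(canonical.labels, canonical.states)}
    labels: list[str] = []
    states: list[tuple[str, ...]] = []
    assignments: dict[str, list[str]] = {}
    index: dict[tuple[str, ...], str] = {}
    novel = 0
    for name, row in state_of.items():
        if row not in index:
            if row in canon:
                label = canon[row]
            else:
                novel += 1
                label = f"H{novel}"
            index[row] = label
            labels.append(label)
            states.append(row)
            assignments[label] = []
        assignments[index[row]].append(name)
    return HaplotypeMatrix(labels, states, used, assignments)


def pairwise_steps(hm: HaplotypeMatrix) -> StepDistanceMatrix:
    """Mutational-step distances: number of characters at which two rows differ."""
    n = len(hm.labels)
    m = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = sum(a != b for a, b in zip(hm.states[i], hm.states[j]))
            m[i, j] = m[j, i] = d
    return StepDistanceMatrix(list(hm.labels), m)
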