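"""File formats: FASTA alignments, TSV tables/matrices, newick, GML.

Thin wrappers over Biopython, pandas and networkx so that every stage of
the pipeline reads and writes plain-text files.
"""

from __future__ import annotations

import os
from collections.abc import Mapping, Sequence
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Phylo, SeqIO

from .diversity import PopulationRecord
from .haplotypes import AlignedSequences, AlignmentError, HaplotypeMatrix, StepDistanceMatrix

__all__ = [
    "read_locus_fastas",
    "write_locus_fastas",
    "read_population_table",
    "write_population_table",
    "read_individual_map",
    "write_haplotype_assignments",
    "write_character_matrix",
    "write_step_matrix",
    "read_step_matrix",
    "write_network",
    "write_tree",
]


def read_locus_fastas(paths: Mapping[str, str | Path]) -> AlignedSequences:
    """Read one aligned FASTA per locus; sequence ids must agree across loci."""
    names: list[str] | None = None
    loci: dict[str, list[str]] = {}
    order: list[str] = []
    for locus, path in paths.items():
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentError(f"no sequences in {path}")
        ids = [r.id for r in records]
        if names is None:
            names = ids
        elif set(ids) != set(names):
            raise AlignmentError(f"locus {locus!r}: sequence ids differ across loci")
        by_id = {r.id: str(r.seq).upper() for r in records}
        loci[locus] = [by_id[n] for n in names]
        order.append(locus)
    assert names is not None
    return AlignedSequences(names, loci, order)


def write_locus_fastas(aln: AlignedSequences, directory: str | Path) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for locus in aln.order:
        path = directory / f"{locus}.fasta"
        with open(path, "w") as fh:
            for name, seq in zip(aln.names, aln.loci[locus]):
                fh.write(f">{name}{os.linesep}{seq}{os.linesep}")
        out[locus] = path
    return out


def read_population_table(path: str | Path) -> list[PopulationRecord]:
    """Population TSV with columns code, location, lon, lat, altitude_m, n, counts.

    ``counts`` holds comma-separated ``haplotype:count`` pairs.
    """
    df = pd.read_csv(path, sep="\t", dtype={"code": str, "counts": str})
    pops = []
    for row in df.itertuples(index=False):
        counts = {}
        for pair in str(row.counts).split(","):
            h, c = pair.split(":")
            counts[h.strip()] = int(c)
        pops.append(
            PopulationRecord(
                code=row.code,
                location=getattr(row, "location", ""),
                lon=float(row.lon),
                lat=float(row.lat),
                altitude_m=float(getattr(row, "altitude_m", 0.0)),
                n=int(row.n),
                counts=counts,
            )
        )
    return pops


def write_population_table(pops: Sequence[PopulationRecord], path: str | Path) -> None:
    rows = []
    for p in pops:
        rows.append(
            {
                "code": p.code,
                "location": p.location,
                "lon": p.lon,
                "lat": p.lat,
                "altitude_m": p.altitude_m,
                "n": p.n,
                "counts": ",".join(f"{h}:{c}" for h, c in sorted(p.counts.items())),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_individual_map(path: str | Path) -> dict[str, str]:
    """TSV mapping individual_id -> population_code."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["individual_id"], df["population_code"]))


def write_haplotype_assignments(hm: HaplotypeMatrix, path: str | Path) -> None:
    rows = [
        {"individual_id": ind, "haplotype": label}
        for label in hm.labels
        for ind in hm.assignments.get(label, [])
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_character_matrix(hm: HaplotypeMatrix, path: str | Path) -> None:
    cols = (
        [f"{s.locus}:{s.kind[0]}{i + 1}" for i, s in enumerate(hm.sites)]
        if hm.sites
        else [f"char{i + 1}" for i in range(hm.n_characters)]
    )
    df = pd.DataFrame(list(map(list, hm.states)), index=hm.labels, columns=cols)
    df.index.name = "haplotype"
    df.to_csv(path, sep="\t")


def write_step_matrix(d: StepDistanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(d.matrix, index=d.labels, columns=d.labels)
    df.index.name = "haplotype"
    df.to_csv(path, sep="\t")


def read_step_matrix(path: str | Path) -> StepDistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return StepDistanceMatrix(list(df.index), df.to_numpy(dtype=int))


def write_network(g: nx.Graph, edge_path: str | Path, gml_path: str | Path | None = None) -> None:
    rows = [
        {"from": a, "to": b, "steps": data.get("steps", 1)}
        for a, b, data in sorted(g.edges(data=True))
    ]
    pd.DataFrame(rows).to_csv(edge_path, sep="\t", index=False)
    if gml_path is not None:
        nx.write_gml(g, str(gml_path))


def write_tree(tree, path: str | Path) -> None:
    Phylo.write(tree, str(path), "newick")


def matrix_to_tsv(labels: Sequence[str], m: np.ndarray, path: str | Path) -> None:
    df = pd.DataFrame(m, index=list(labels), columns=list(labels))
    df.index.name = "code"
    df.to_csv(path, sep="\t")
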