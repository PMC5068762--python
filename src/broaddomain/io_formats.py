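"""Readers and writers for every external format the pipeline touches.

Formats: UCSC two-column chrom.sizes, BED3/BED6 peak files, TSV edge lists,
TSV expression matrices and refFlat-style gene-model tables.  Readers reject
malformed records (with line numbers) rather than silently repairing them;
``read_x(write_x(obj)) == obj`` on valid inputs.

Coordinates are 0-based half-open internally.  Browser-style 1-based
fully-closed input is supported via ``one_based=True`` on :func:`read_bed`.
Chromosome names are matched verbatim everywhere: silent "chr" aliasing
corrupts cross-species comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

import networkx as nx
import numpy as np
import pandas as pd

from .core_intervals import Peak, PeakSet

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

__all__ = [
    "GenomeLayout",
    "ParseError",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_edge_list",
    "write_edge_list",
    "read_expression",
    "write_expression",
    "read_gene_models",
    "write_gene_models",
]


class ParseError(ValueError):
    """A malformed record in an input file; message carries the line number."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome-name -> length (bp) map.

    Defines the coordinate frame for interval validity and the support of the
    genome-wide shuffle null.
    """

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome layout")
        for name, length in self.entries:
            if not name:
                raise ValueError("empty chromosome name")
            if length <= 0:
                raise ValueError(f"non-positive length {length} for {name}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.entries)

    @property
    def sizes(self) -> dict[str, int]:
        return dict(self.entries)

    @property
    def total_size(self) -> int:
        return sum(l for _, l in self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self.sizes

    def __len__(self) -> int:
        return len(self.entries)

    def validate_peaks(self, peaks: PeakSet) -> None:
        sizes = self.sizes
        for p in peaks:
            if p.chrom not in sizes:
                raise ValueError(f"peak chromosome {p.chrom!r} not in genome layout")
            if p.end > sizes[p.chrom]:
                raise ValueError(
                    f"peak {p.chrom}:{p.start}-{p.end} exceeds chromosome "
                    f"length {sizes[p.chrom]}"
                )


def read_chrom_sizes(path: PathLike) -> GenomeLayout:
    """Read a UCSC-style two-column (name, length) chrom.sizes file."""
    entries = []
    seen = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'name length', got {line!r}")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: length {fields[1]!r} is not an integer")
            if length <= 0:
                raise ParseError(f"{path}:{lineno}: non-positive length {length}")
            if name in seen:
                raise ParseError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            seen.add(name)
            entries.append((name, length))
    if not entries:
        raise ParseError(f"{path}: no chromosomes")
    return GenomeLayout(tuple(entries))


def write_chrom_sizes(genome: GenomeLayout, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, length in genome.entries:
            fh.write(f"{name}\t{length}\n")


def read_bed(
    path: PathLike,
    cell_type: Optional[str] = None,
    cohort: Optional[str] = None,
    one_based: bool = False,
) -> PeakSet:
    """Read a BED3/BED6 peak file into a sorted PeakSet.

    ``one_based=True`` treats coordinates as 1-based fully-closed (browser
    style) and converts to 0-based half-open on input.  Strand (column 6) is
    read and discarded: H3K4me3 peaks are unstranded.
    """
    peaks = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates")
            if one_based:
                start -= 1
            if start >= end:
                raise ParseError(
                    f"{path}:{lineno}: start >= end ({chrom}:{start}-{end})"
                )
            if start < 0:
                raise ParseError(f"{path}:{lineno}: negative start {start}")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = 0.0
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-numeric score {fields[4]!r}")
            peaks.append(
                Peak(chrom, start, end, name=name, score=score,
                     cell_type=cell_type, cohort=cohort)
            )
    return PeakSet(peaks, provenance=str(path))


def write_bed(peaks: PeakSet, path: PathLike) -> None:
    """Write a PeakSet as sorted, newline-terminated BED6.

    Missing names become "." and missing scores 0; scores that are whole
    numbers are written as integers so round-trips are exact.
    """
    with open(path, "w") as fh:
        for p in peaks:
            score = int(p.score) if float(p.score).is_integer() else p.score
            name = p.name if p.name is not None else "."
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{score}\t.\n")


def read_edge_list(path: PathLike) -> nx.Graph:
    """Read a two-column TSV of gene-gene edges as a simple undirected graph.

    Self-loops are dropped (logged), duplicate and reversed duplicate edges
    collapse; any direction in the input is discarded.
    """
    graph = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected two gene ids")
            u, v = fields[0].strip(), fields[1].strip()
            if not u or not v:
                raise ParseError(f"{path}:{lineno}: blank gene id")
            if u == v:
                n_self += 1
                graph.add_node(u)
                continue
            graph.add_edge(u, v)
    if n_self:
        logger.warning("%s: dropped %d self-loop(s)", path, n_self)
    return graph


def write_edge_list(graph: nx.Graph, path: PathLike) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{u}\t{v}\n")


def read_expression(
    path: PathLike,
    metadata: Union[PathLike, Mapping[str, Mapping[str, str]], pd.DataFrame],
):
    """Read a gene x sample FPKM TSV plus sample metadata.

    ``metadata`` maps sample -> {subject, compartment} (dict, DataFrame
    indexed by sample, or a TSV path with columns sample/subject/compartment).
    Samples missing from the metadata are rejected by name.
    """
    from .expression_qc import ExpressionMatrix  # local import: avoid cycle

    values = pd.read_csv(path, sep="\t", index_col=0)
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene id {dup!r}")
    arr = values.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ParseError(f"{path}: non-numeric expression values")
    if (arr < 0).any():
        gene = values.index[np.argwhere(arr < 0)[0][0]]
        raise ValueError(f"{path}: negative FPKM for gene {gene!r}")
    if isinstance(metadata, (str, Path)):
        meta = pd.read_csv(metadata, sep="\t", index_col=0)
    elif isinstance(metadata, pd.DataFrame):
        meta = metadata.copy()
    else:
        meta = pd.DataFrame.from_dict(dict(metadata), orient="index")
    missing = [s for s in values.columns if s not in meta.index]
    if missing:
        raise KeyError(f"samples missing from metadata: {missing}")
    meta = meta.loc[list(values.columns)]
    return ExpressionMatrix(values=values, meta=meta)


def write_expression(expr, values_path: PathLike, meta_path: Optional[PathLike] = None) -> None:
    expr.values.to_csv(values_path, sep="\t", index_label="gene_id")
    if meta_path is not None:
        expr.meta.to_csv(meta_path, sep="\t", index_label="sample")


def read_gene_models(path: PathLike):
    """Read a refFlat-style gene-model TSV.

    Columns: gene_id, chrom, strand, tss, tes, exon_starts, exon_ends (the
    last two comma-separated, possibly with a trailing comma).
    """
    from .annotation import GeneModel  # local import: avoid cycle

    models = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ParseError(f"{path}:{lineno}: expected 7 gene-model columns")
            gene_id, chrom, strand = fields[0], fields[1], fields[2]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            try:
                tss, tes = int(fields[3]), int(fields[4])
                starts = [int(x) for x in fields[5].split(",") if x]
                ends = [int(x) for x in fields[6].split(",") if x]
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate")
            if len(starts) != len(ends):
                raise ParseError(f"{path}:{lineno}: exon start/end count mismatch")
            models.append(
                GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                          tss=tss, tes=tes, exons=tuple(zip(starts, ends)))
            )
    return models


def write_gene_models(models, path: PathLike) -> None:
    with open(path, "w") as fh:
        for g in models:
            starts = ",".join(str(s) for s, _ in g.exons)
            ends = ",".join(str(e) for _, e in g.exons)
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.tes}\t{starts}\t{ends}\n")
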