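"""Readers, writers and design validation.

All interchange is tab-separated UTF-8 text with a mandatory header row
and '.' decimals. Gene identifiers are opaque strings; no normalization
is attempted. Missing fold-change values are written as ``NA`` and read
back as flagged-missing (NaN), never as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import pandas as pd

from .types import (
    CountMatrix,
    FoldChangeTensor,
    InputError,
    SampleAnnotation,
    ValidationError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .network import CoexpressionNetwork

logger = logging.getLogger(__name__)

_SHEET_COLUMNS = ["sample_id", "genotype", "time_h", "replicate", "assay"]


def read_sample_sheet(path: str | Path) -> list[SampleAnnotation]:
    """Parse a sample sheet TSV with columns sample_id, genotype, time_h,
    replicate, assay."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"sample sheet not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _SHEET_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"sample sheet missing columns {missing}")
    out = []
    for row in table.itertuples(index=False):
        try:
            time_h = int(row.time_h)
            replicate = int(row.replicate)
        except ValueError as exc:
            raise ValidationError(
                f"sample {row.sample_id}: time_h/replicate must be integers"
            ) from exc
        out.append(
            SampleAnnotation(
                sample_id=str(row.sample_id),
                genotype=str(row.genotype),
                time_h=time_h,
                replicate=replicate,
                assay=str(row.assay),
            )
        )
    return out


def write_sample_sheet(samples: Sequence[SampleAnnotation], path: str | Path) -> None:
    table = pd.DataFrame(
        [[s.sample_id, s.genotype, s.time_h, s.replicate, s.assay] for s in samples],
        columns=_SHEET_COLUMNS,
    )
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_count_matrix(path: str | Path, sample_sheet_path: str | Path) -> CountMatrix:
    """Read a counts TSV (header = sample ids, first column = gene ids)
    and attach annotations from the sample sheet.

    Sample order follows the count-file header; every count column must
    have a sheet row and vice versa.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"count matrix not found: {path}")
    sheet = {s.sample_id: s for s in read_sample_sheet(sample_sheet_path)}
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    missing = [c for c in raw.columns if c not in sheet]
    if missing:
        raise ValidationError(f"count columns missing from sample sheet: {missing}")
    # a combined sheet may describe both assays; rows for the other assay
    # are ignored, but unmatched rows of the matrix's own assay(s) are an
    # inconsistency
    matched_assays = {sheet[c].assay for c in raw.columns}
    unused = [
        sid for sid, s in sheet.items()
        if sid not in raw.columns and s.assay in matched_assays
    ]
    if unused:
        raise ValidationError(f"sample sheet rows lacking a count column: {unused}")
    samples = [sheet[c] for c in raw.columns]
    return CountMatrix(raw, samples)


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    """One gene id per line, order preserved; an empty list yields an
    empty file."""
    try:
        with open(path, "w", encoding="utf-8") as fh:
            for g in genes:
                fh.write(f"{g}\n")
    except OSError as exc:
        raise InputError(f"cannot write gene list to {path}: {exc}") from exc


def read_gene_list(path: str | Path) -> list[str]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"gene list not found: {path}")
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_fold_change(tensor: FoldChangeTensor, path: str | Path) -> None:
    """Long-format fc table (gene, genotype, time_h, log2fc, baseline);
    missing values serialized as NA."""
    long = tensor.to_long()
    long.to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%.10g",
        lineterminator="\n",
    )


def read_fold_change(path: str | Path) -> FoldChangeTensor:
    path = Path(path)
    if not path.exists():
        raise InputError(f"fold-change table not found: {path}")
    long = pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=False,
        dtype={"gene": str, "genotype": str},
    )
    return FoldChangeTensor.from_long(long)


def write_network(network: "CoexpressionNetwork", path_prefix: str | Path) -> tuple[Path, Path]:
    """Write a network as an edge-list TSV and a GraphML file.

    Returns the (edge list, GraphML) paths. Output is byte-stable for
    identical inputs: edges are sorted lexicographically and r values are
    printed with 12 decimals.
    """
    import networkx as nx

    prefix = Path(path_prefix)
    edge_path = prefix.with_suffix(".edges.tsv")
    graphml_path = prefix.with_suffix(".graphml")
    rows = sorted((e.gene_a, e.gene_b, e.r, e.sign) for e in network.edges)
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tr\tsign\n")
        for a, b, r, sign in rows:
            fh.write(f"{a}\t{b}\t{r:.12f}\t{sign}\n")
    graph = nx.Graph(genotype=network.genotype)
    for node in sorted(network.nodes):
        graph.add_node(node)
    for a, b, r, sign in rows:
        graph.add_edge(a, b, r=round(r, 12), sign=sign)
    nx.write_graphml(graph, graphml_path)
    return edge_path, graphml_path


def read_network_edges(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"edge list not found: {path}")
    return pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})


@dataclass
class DesignReport:
    """Replicate coverage of every genotype x time cell, plus flags."""

    cells: pd.DataFrame  # columns: genotype, time_h, n_replicates
    flags: list[str]

    @property
    def genotypes(self) -> list[str]:
        return list(self.cells["genotype"].unique())

    @property
    def times(self) -> list[int]:
        return sorted(self.cells["time_h"].unique())


def validate_design(matrix: CountMatrix, control_time_h: int = 0) -> DesignReport:
    """Report replicate counts for every genotype x time cell and flag
    genotypes lacking a control (0 h) sample. Report-only: never raises
    for design gaps and never mutates its input."""
    genotypes = matrix.genotypes
    times = sorted({s.time_h for s in matrix.samples})
    rows = []
    for g in genotypes:
        for t in times:
            rows.append((g, t, len(matrix.samples_for(genotype=g, time_h=t))))
    cells = pd.DataFrame(rows, columns=["genotype", "time_h", "n_replicates"])
    flags = [
        f"no control sample: {g}"
        for g in genotypes
        if not matrix.samples_for(genotype=g, time_h=control_time_h)
    ]
    for row in cells.itertuples(index=False):
        if 0 < row.n_replicates < 2:
            logger.info(
                "design cell %s/%sh has %d replicate(s)",
                row.genotype, row.time_h, row.n_replicates,
            )
    return DesignReport(cells=cells, flags=flags)
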