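"""miRNA family aggregation, per-genotype spread statistics, and
miRNA-target anti-correlation screening.

Near-identical annotated miRNAs are collapsed into families (a supplied
id -> family map) before any expression analysis, to avoid double
counting highly similar mature sequences. Per-genotype "range"
statistics (min, max, IQR, SD of pooled family fold changes) formalize
the narrow-vs-wide spread comparison across genotypes. Finally, supplied
(family, target gene) pairs are screened for repression-consistent
expression: a strongly negative Pearson correlation between the family's
temporal fold-change profile and the target's, per genotype.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import pcc
from .types import CountMatrix, FoldChangeTensor, InputError, UsageError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "read_family_map",
    "write_family_map",
    "collapse_families",
    "family_range_stats",
    "pair_correlation",
    "read_pair_list",
    "write_pair_list",
]


def read_family_map(path: str | Path) -> dict[str, str]:
    """TSV with columns mirna_id, family; every id maps to one family."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"family map not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"mirna_id", "family"}.issubset(table.columns):
        raise ValidationError("family map needs columns mirna_id, family")
    if table["mirna_id"].duplicated().any():
        dup = table.loc[table["mirna_id"].duplicated(), "mirna_id"].iloc[0]
        raise ValidationError(f"miRNA id {dup!r} mapped to more than one family")
    return dict(zip(table["mirna_id"], table["family"]))


def write_family_map(family_map: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(family_map.items()), columns=["mirna_id", "family"]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_pair_list(path: str | Path) -> list[tuple[str, str]]:
    """TSV with columns family, gene_id."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"pair list not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"family", "gene_id"}.issubset(table.columns):
        raise ValidationError("pair list needs columns family, gene_id")
    return list(zip(table["family"], table["gene_id"]))


def write_pair_list(pairs: Sequence[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(pairs, columns=["family", "gene_id"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def collapse_families(
    mirna_counts: CountMatrix,
    family_map: Mapping[str, str],
    mode: Literal["sum", "mean"] = "sum",
    drop_unmapped: bool = True,
) -> CountMatrix:
    """Collapse member miRNAs into one count row per family.

    ``sum`` (default) preserves abundance semantics — per-sample totals
    over retained members are conserved; ``mean`` averages members
    (rounded to the nearest integer count).
    """
    if not family_map:
        raise UsageError("family map is empty")
    ids = mirna_counts.gene_ids
    unmapped = [i for i in ids if i not in family_map]
    if unmapped:
        if not drop_unmapped:
            raise ValidationError(f"unmapped miRNA ids: {unmapped[:10]}")
        logger.warning("dropping %d unmapped miRNA ids", len(unmapped))
    mapped = [i for i in ids if i in family_map]
    counts = mirna_counts.counts.loc[mapped]
    fams = pd.Series([family_map[i] for i in mapped], index=counts.index, name="family")
    grouped = counts.groupby(fams, sort=False)
    if mode == "sum":
        out = grouped.sum()
    elif mode == "mean":
        out = grouped.mean().round().astype(np.int64)
    else:
        raise UsageError(f"unknown collapse mode {mode!r}")
    out.index.name = "gene_id"
    return CountMatrix(out, list(mirna_counts.samples))


def family_range_stats(family_fc: FoldChangeTensor) -> pd.DataFrame:
    """Pool every family x stress-time fc per genotype and report
    n, min, max, IQR (linear-interpolation quartiles) and SD (n-1).

    A genotype with a single finite value gets SD = NaN (flagged
    missing).
    """
    if not family_fc.gene_ids or not family_fc.stress_times_h:
        raise UsageError("need at least one family and one stress time")
    rows = []
    for g in family_fc.genotypes:
        pooled = family_fc.genotype_block(g).to_numpy(dtype=float).ravel()
        pooled = pooled[np.isfinite(pooled)]
        n = pooled.size
        if n == 0:
            rows.append((g, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        q75, q25 = np.percentile(pooled, [75, 25])
        sd = float(np.std(pooled, ddof=1)) if n > 1 else np.nan
        rows.append((g, n, float(pooled.min()), float(pooled.max()), float(q75 - q25), sd))
    return pd.DataFrame(
        rows, columns=["genotype", "n_values", "min", "max", "iqr", "sd"]
    )


def pair_correlation(
    family_fc: FoldChangeTensor,
    target_fc: FoldChangeTensor,
    pairs: Sequence[tuple[str, str]],
    rho: float = 0.8,
    include_control_zero: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-genotype correlation between family and target fc profiles.

    Returns (table, problems): one row per pair x genotype with r and
    the repression-consistency flag (r <= -rho); unknown families or
    genes are listed in ``problems`` while remaining pairs are still
    processed. Zero-variance profiles yield missing r and a False flag.
    """
    genotypes = family_fc.genotypes
    problems = []
    rows = []
    for family, gene in pairs:
        if family not in family_fc.fc.index:
            problems.append(f"unknown family {family!r}")
            continue
        if gene not in target_fc.fc.index:
            problems.append(f"unknown target gene {gene!r}")
            continue
        for g in genotypes:
            fam = family_fc.profile(family, g)
            tgt = target_fc.profile(gene, g)
            if include_control_zero:
                fam = np.concatenate([[0.0], fam])
                tgt = np.concatenate([[0.0], tgt])
            usable = np.isfinite(fam) & np.isfinite(tgt)
            if usable.sum() < 3:
                r = float("nan")
            else:
                r = pcc(fam[usable], tgt[usable])
            consistent = bool(np.isfinite(r) and r <= -rho)
            rows.append((family, gene, g, r, consistent))
    table = pd.DataFrame(
        rows, columns=["family", "gene", "genotype", "r", "repression_consistent"]
    )
    return table, problems
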