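"""Per-gene, per-genotype response classification and set intersections.

A gene responds in a genotype if its log2-FC exceeds the threshold
(strictly) at *any* stress time: up if fc > +2, down if fc < -2, constant
only when neither fires at any time point. The two flags are independent,
so a gene can be both up and down ("mixed") — the three published panels
are recoverable as up = up_only + mixed, down = down_only + mixed.

Cross-genotype comparisons use exclusive (UpSet) semantics: each gene in
a category is attributed to exactly the subset of genotypes whose set it
belongs to, so exclusive counts over all subsets sum to the union size.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .types import FoldChangeTensor, UsageError

__all__ = [
    "ResponseCall",
    "IntersectionTable",
    "classify_gene",
    "classify_all",
    "set_intersections",
]

Category = Literal["constant", "up_only", "down_only", "mixed", "unclassifiable"]


@dataclass(frozen=True)
class ResponseCall:
    gene_id: str
    genotype: str
    up: bool
    down: bool
    category: Category


def _categorize(up: bool, down: bool) -> Category:
    if up and down:
        return "mixed"
    if up:
        return "up_only"
    if down:
        return "down_only"
    return "constant"


def classify_gene(
    fc_vector: Iterable[float], threshold: float = 2.0,
    gene_id: str = "", genotype: str = "",
) -> ResponseCall:
    """Classify one temporal fc vector; strict inequalities at the
    threshold (fc == 2.0 exactly does not fire). All-missing vectors are
    flagged unclassifiable, not an error."""
    fc = np.asarray(list(fc_vector), dtype=float)
    if fc.size == 0:
        raise UsageError("empty fold-change vector")
    finite = fc[np.isfinite(fc)]
    if finite.size == 0:
        return ResponseCall(gene_id, genotype, False, False, "unclassifiable")
    up = bool(np.any(finite > threshold))
    down = bool(np.any(finite < -threshold))
    return ResponseCall(gene_id, genotype, up, down, _categorize(up, down))


def classify_all(tensor: FoldChangeTensor, threshold: float = 2.0) -> pd.DataFrame:
    """One call per gene x genotype, as a table with columns
    gene, genotype, up, down, category (vectorized over the tensor)."""
    frames = []
    for g in tensor.genotypes:
        block = tensor.genotype_block(g).to_numpy(dtype=float)
        finite = np.isfinite(block)
        any_finite = finite.any(axis=1)
        up = np.any(np.where(finite, block, 0.0) > threshold, axis=1)
        down = np.any(np.where(finite, block, 0.0) < -threshold, axis=1)
        cats = np.select(
            [~any_finite, up & down, up, down],
            ["unclassifiable", "mixed", "up_only", "down_only"],
            default="constant",
        )
        frames.append(
            pd.DataFrame(
                {
                    "gene": tensor.gene_ids,
                    "genotype": g,
                    "up": up & any_finite,
                    "down": down & any_finite,
                    "category": cats,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def summarize_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype counts per category (long format)."""
    out = (
        calls.groupby(["genotype", "category"], sort=False)
        .size()
        .rename("n_genes")
        .reset_index()
    )
    return out


@dataclass
class IntersectionTable:
    """Exclusive UpSet-style intersection counts for one category.

    ``exclusive_counts`` maps every non-empty genotype subset (as a
    sorted tuple) to the number of genes whose membership is exactly that
    subset; ``totals`` maps each genotype to its full set size.
    """

    category: str
    genotypes: list[str]
    exclusive_counts: Mapping[tuple[str, ...], int]
    totals: Mapping[str, int]

    @property
    def union_size(self) -> int:
        return int(sum(self.exclusive_counts.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subset": ",".join(k), "degree": len(k), "exclusive_count": v}
            for k, v in self.exclusive_counts.items()
        ]
        return pd.DataFrame(rows)


def set_intersections(
    calls: pd.DataFrame, which: Literal["up", "down", "constant"]
) -> IntersectionTable:
    """Exclusive intersection counts of the up / down / constant gene
    sets across genotypes. Unclassifiable genes are excluded."""
    if which not in ("up", "down", "constant"):
        raise UsageError(f"unknown category {which!r}")
    genotypes = list(calls["genotype"].unique())
    if len(genotypes) < 2:
        raise UsageError("set intersections need at least 2 genotypes")
    usable = calls[calls["category"] != "unclassifiable"]
    if which == "constant":
        member = usable[usable["category"] == "constant"]
    else:
        member = usable[usable[which]]
    sets = {g: set(member.loc[member["genotype"] == g, "gene"]) for g in genotypes}
    membership: dict[str, tuple[str, ...]] = {}
    for g in genotypes:
        for gene in sets[g]:
            membership.setdefault(gene, ())
    for gene in membership:
        membership[gene] = tuple(g for g in genotypes if gene in sets[g])
    exclusive: dict[tuple[str, ...], int] = {}
    for degree in range(1, len(genotypes) + 1):
        for subset in combinations(genotypes, degree):
            exclusive[subset] = 0
    for subset in membership.values():
        exclusive[subset] += 1
    totals = {g: len(sets[g]) for g in genotypes}
    return IntersectionTable(
        category=which, genotypes=genotypes, exclusive_counts=exclusive, totals=totals
    )
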