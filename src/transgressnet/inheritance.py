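"""Parental-inheritance tracing of expression patterns in RILs.

Each gene's temporal response in a RIL is compared against both parents
after discretizing every log2-FC into a per-time code: +1 (up beyond the
threshold), -1 (down), or 0 (inside the constant band). Two profiles
"match" when their codes agree at every compared time point. A gene is
then assigned one of five categories per RIL:

- ``complete``      the RIL matches both parents (which forces the
                    parents to match each other),
- ``parentA_like``  the RIL matches parent A only,
- ``parentB_like``  the RIL matches parent B only,
- ``non_parental``  the RIL matches neither parent (deviant /
                    transgressive expression),
- ``excluded``      the trio's data are unusable: near-zero abundance
                    throughout, or an extreme outlying fold change.

Discretization deliberately reuses the published +/-2 log2-FC rule so
"same expression pattern" has exactly the granularity of the response
classification. A continuous alternative (Chebyshev distance on the raw
fc vectors) is available via ``match_mode="chebyshev"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .normalization import low_abundance_mask
from .types import FoldChangeTensor, NormalizedMatrix, Thresholds, UsageError

__all__ = [
    "InheritanceCall",
    "discretize_profile",
    "trace_gene",
    "trace_all",
    "TraceResult",
]

CATEGORIES = ("complete", "parentA_like", "parentB_like", "non_parental", "excluded")

ExclusionReason = Literal["none", "low_abundance", "outlier"]


@dataclass(frozen=True)
class InheritanceCall:
    gene_id: str
    ril: str
    category: str
    exclusion_reason: ExclusionReason = "none"
    ril_codes: tuple | None = None
    parent_a_codes: tuple | None = None
    parent_b_codes: tuple | None = None


def discretize_profile(
    fc_vector: Iterable[float], threshold: float = 2.0
) -> np.ndarray:
    """Per-time codes in {-1, 0, +1}; strict inequalities at the
    threshold; missing (NaN) stays missing."""
    fc = np.asarray(list(fc_vector), dtype=float)
    codes = np.zeros(fc.shape, dtype=float)
    codes[fc > threshold] = 1.0
    codes[fc < -threshold] = -1.0
    codes[~np.isfinite(fc)] = np.nan
    return codes


def _codes_match(x: np.ndarray, y: np.ndarray, compared: np.ndarray) -> bool:
    return bool(np.all(x[compared] == y[compared]))


def trace_gene(
    ril_codes: Sequence[float],
    parent_a_codes: Sequence[float],
    parent_b_codes: Sequence[float],
    excluded: ExclusionReason = "none",
    gene_id: str = "",
    ril: str = "",
) -> InheritanceCall:
    """Assign one gene in one RIL to a parental-origin category.

    Time points with a missing code in any of the three profiles are
    dropped; if none remain the gene is excluded as low-abundance.
    """
    r = np.asarray(ril_codes, dtype=float)
    a = np.asarray(parent_a_codes, dtype=float)
    b = np.asarray(parent_b_codes, dtype=float)
    if not (r.shape == a.shape == b.shape):
        raise UsageError("code vectors must share length")
    if excluded != "none":
        return InheritanceCall(gene_id, ril, "excluded", excluded)
    compared = np.isfinite(r) & np.isfinite(a) & np.isfinite(b)
    if not np.any(compared):
        return InheritanceCall(gene_id, ril, "excluded", "low_abundance")
    match_a = _codes_match(r, a, compared)
    match_b = _codes_match(r, b, compared)
    if match_a and match_b:
        category = "complete"
    elif match_a:
        category = "parentA_like"
    elif match_b:
        category = "parentB_like"
    else:
        category = "non_parental"
    return InheritanceCall(
        gene_id,
        ril,
        category,
        "none",
        tuple(r[compared]),
        tuple(a[compared]),
        tuple(b[compared]),
    )


@dataclass
class TraceResult:
    """Full inheritance table plus summary counts."""

    calls: pd.DataFrame  # gene, ril, category, exclusion_reason
    category_counts: pd.DataFrame  # ril x category
    shared_counts: pd.DataFrame  # ril_a, ril_b, category, n_shared


def _chebyshev_match(x: np.ndarray, y: np.ndarray, compared: np.ndarray, delta: float) -> bool:
    return bool(np.max(np.abs(x[compared] - y[compared])) <= delta)


def trace_all(
    tensor: FoldChangeTensor,
    norm: NormalizedMatrix,
    parent_a: str,
    parent_b: str,
    rils: Sequence[str],
    thresholds: Thresholds = Thresholds(),
    match_mode: Literal["codes", "chebyshev"] = "codes",
    chebyshev_delta: float = 1.0,
    min_samples: int = 2,
) -> TraceResult:
    """Trace every gene in every RIL against the two parents.

    Exclusions are applied per trio (RIL + both parents) before
    matching: ``low_abundance`` when the gene never reaches the cutoff
    within the trio's samples, ``outlier`` when any |fc| in the trio
    exceeds the cap.
    """
    for p in (parent_a, parent_b):
        if p in rils:
            raise UsageError(f"parent {p!r} also listed as RIL")
        if p not in tensor.genotypes:
            raise UsageError(f"parent {p!r} absent from tensor")
    for ril in rils:
        if ril not in tensor.genotypes:
            raise UsageError(f"RIL {ril!r} absent from tensor")

    genes = tensor.gene_ids
    times = tensor.stress_times_h
    blocks = {
        g: tensor.genotype_block(g).to_numpy(dtype=float)
        for g in [parent_a, parent_b, *rils]
    }
    codes = {
        g: discretize_profile(blocks[g].ravel(), thresholds.fc_threshold).reshape(
            blocks[g].shape
        )
        for g in blocks
    }
    rows = []
    for ril in rils:
        trio_samples = [
            s.sample_id
            for s in norm.samples
            if s.genotype in (ril, parent_a, parent_b)
        ]
        keep = low_abundance_mask(
            norm,
            cutoff=thresholds.low_abundance_cutoff,
            min_samples=min_samples,
            sample_ids=trio_samples,
        ).reindex(genes)
        trio_fc = np.stack([blocks[ril], blocks[parent_a], blocks[parent_b]])
        with np.errstate(invalid="ignore"):
            outlier = np.any(np.abs(trio_fc) > thresholds.outlier_cap, axis=(0, 2))
        for i, gene in enumerate(genes):
            if not bool(keep.iloc[i]):
                reason: ExclusionReason = "low_abundance"
            elif outlier[i]:
                reason = "outlier"
            else:
                reason = "none"
            if reason != "none":
                rows.append((gene, ril, "excluded", reason))
                continue
            r, a, b = codes[ril][i], codes[parent_a][i], codes[parent_b][i]
            compared = np.isfinite(r) & np.isfinite(a) & np.isfinite(b)
            if not np.any(compared):
                rows.append((gene, ril, "excluded", "low_abundance"))
                continue
            if match_mode == "chebyshev":
                fr, fa, fb = blocks[ril][i], blocks[parent_a][i], blocks[parent_b][i]
                match_a = _chebyshev_match(fr, fa, compared, chebyshev_delta)
                match_b = _chebyshev_match(fr, fb, compared, chebyshev_delta)
            else:
                match_a = _codes_match(r, a, compared)
                match_b = _codes_match(r, b, compared)
            if match_a and match_b:
                category = "complete"
            elif match_a:
                category = "parentA_like"
            elif match_b:
                category = "parentB_like"
            else:
                category = "non_parental"
            rows.append((gene, ril, category, "none"))
    calls = pd.DataFrame(rows, columns=["gene", "ril", "category", "exclusion_reason"])

    counts = (
        calls.pivot_table(
            index="ril", columns="category", values="gene", aggfunc="count", fill_value=0
        )
        .reindex(columns=list(CATEGORIES), fill_value=0)
        .reindex(list(rils))
    )
    counts.columns.name = None

    shared_rows = []
    by_ril = {
        ril: calls[calls["ril"] == ril].set_index("gene")["category"] for ril in rils
    }
    for i, ra in enumerate(rils):
        for rb in rils[i + 1 :]:
            same = by_ril[ra] == by_ril[rb].reindex(by_ril[ra].index)
            for cat in CATEGORIES:
                n = int(((by_ril[ra] == cat) & same).sum())
                shared_rows.append((ra, rb, cat, n))
    shared = pd.DataFrame(shared_rows, columns=["ril_a", "ril_b", "category", "n_shared"])
    return TraceResult(calls=calls, category_counts=counts, shared_counts=shared)
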