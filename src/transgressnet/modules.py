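"""Selection of the two transgressive gene modules for a focal genotype.

``select_steady_upregulated`` collects genes induced beyond the
threshold at *every* stress time in the focal genotype — the steadily
upregulated, putatively growth-sustaining set. It can be refined by an
early-time contrast: keep only members that are simultaneously
downregulated at 24 h in every inferior genotype, isolating responses
unique to the focal line.

``select_constitutive`` collects genes whose 0-h baseline in the focal
genotype exceeds the parental mean by more than ``base_threshold`` log2
units while their fold changes stay strictly inside the constant band at
every stress time — constitutively high expression unaffected by stress.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Literal, Sequence

import logging
import numpy as np

from .types import FoldChangeTensor, UsageError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModule",
    "select_steady_upregulated",
    "refine_by_early_contrast",
    "select_constitutive",
]


@dataclass
class GeneModule:
    """An ordered gene set plus the rule that produced it.

    ``rule`` records every criterion and parameter so re-running the
    selection on the same tensor is idempotent.
    """

    label: str
    focal_genotype: str
    rule: dict[str, Any] = field(default_factory=dict)
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise UsageError("module members must be unique")

    def __len__(self) -> int:
        return len(self.members)


def select_steady_upregulated(
    tensor: FoldChangeTensor, focal: str, threshold: float = 2.0
) -> GeneModule:
    """Genes with fc > threshold at EVERY stress time in the focal
    genotype; a missing fc at any time disqualifies the gene."""
    block = tensor.genotype_block(focal).to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        selected = np.all(np.nan_to_num(block, nan=-np.inf) > threshold, axis=1)
    members = [g for g, s in zip(tensor.gene_ids, selected) if s]
    return GeneModule(
        label="steady_upregulated",
        focal_genotype=focal,
        rule={"criterion": "fc_above_threshold_all_times", "threshold": threshold},
        members=members,
    )


def refine_by_early_contrast(
    module: GeneModule,
    tensor: FoldChangeTensor,
    inferior: Sequence[str],
    early_time_h: int = 24,
    down_rule: Literal["strict", "lenient"] = "lenient",
    threshold: float = 2.0,
) -> GeneModule:
    """Keep members downregulated at the early time in EVERY inferior
    genotype: ``lenient`` means fc < 0, ``strict`` means fc <= -threshold.
    Output is always a subset of the input module."""
    if not inferior:
        raise UsageError("inferior genotype list must be non-empty")
    if early_time_h not in tensor.stress_times_h:
        raise UsageError(f"early time {early_time_h} h absent from tensor")
    for g in inferior:
        if g not in tensor.genotypes:
            raise UsageError(f"unknown genotype {g!r}")
    kept = []
    for gene in module.members:
        ok = True
        for g in inferior:
            fc = tensor.fc.loc[gene, (g, early_time_h)]
            if not np.isfinite(fc):
                ok = False
                break
            if down_rule == "strict":
                ok = fc <= -threshold
            else:
                ok = fc < 0
            if not ok:
                break
        if ok:
            kept.append(gene)
    rule = dict(module.rule)
    rule.update(
        {
            "refined_by": "early_inferior_contrast",
            "early_time_h": early_time_h,
            "down_rule": down_rule,
            "inferior": list(inferior),
        }
    )
    return GeneModule(
        label=module.label + "_refined",
        focal_genotype=module.focal_genotype,
        rule=rule,
        members=kept,
    )


def select_constitutive(
    tensor: FoldChangeTensor,
    focal: str,
    parents: tuple[str, str],
    base_threshold: float = 2.0,
    stability_threshold: float = 2.0,
    pseudocount: float = 1.0,
    baseline_rule: Literal["parental_mean", "both_parents"] = "parental_mean",
) -> GeneModule:
    """Genes constitutively high in the focal genotype.

    Selection requires (a) a 0-h baseline more than ``base_threshold``
    log2 units above the parental mean (or above BOTH parents when
    ``baseline_rule='both_parents'``) and (b) |fc| strictly below the
    stability threshold at every stress time in the focal genotype.
    Genes with a missing baseline are skipped with a logged warning.
    """
    if focal not in tensor.genotypes:
        raise UsageError(f"unknown genotype {focal!r}")
    for p in parents:
        if p not in tensor.genotypes:
            raise UsageError(f"unknown parent {p!r}")
    block = tensor.genotype_block(focal).to_numpy(dtype=float)
    base_f = tensor.baseline[focal].to_numpy(dtype=float)
    base_a = tensor.baseline[parents[0]].to_numpy(dtype=float)
    base_b = tensor.baseline[parents[1]].to_numpy(dtype=float)
    members = []
    n_skipped = 0
    for i, gene in enumerate(tensor.gene_ids):
        if not (np.isfinite(base_f[i]) and np.isfinite(base_a[i]) and np.isfinite(base_b[i])):
            n_skipped += 1
            continue
        if baseline_rule == "both_parents":
            ratio_ok = all(
                np.log2((base_f[i] + pseudocount) / (p + pseudocount)) > base_threshold
                for p in (base_a[i], base_b[i])
            )
        else:
            parental_mean = 0.5 * (base_a[i] + base_b[i])
            ratio_ok = (
                np.log2((base_f[i] + pseudocount) / (parental_mean + pseudocount))
                > base_threshold
            )
        if not ratio_ok:
            continue
        fc = block[i]
        if np.any(~np.isfinite(fc)) or np.any(np.abs(fc) >= stability_threshold):
            continue
        members.append(gene)
    if n_skipped:
        logger.warning("select_constitutive: skipped %d genes with missing baselines", n_skipped)
    return GeneModule(
        label="constitutive_high",
        focal_genotype=focal,
        rule={
            "criterion": "baseline_ratio_and_stability",
            "base_threshold": base_threshold,
            "stability_threshold": stability_threshold,
            "pseudocount": pseudocount,
            "baseline_rule": baseline_rule,
            "parents": list(parents),
        },
        members=members,
    )
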