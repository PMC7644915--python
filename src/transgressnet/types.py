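"""Core domain types shared by every pipeline stage.

The pipeline operates on three central containers:

``CountMatrix``
    raw gene x sample read counts together with per-sample annotations
    (genotype, hours after stress onset, replicate, assay).

``NormalizedMatrix``
    the same table on a counts-per-million scale after between-sample
    scaling (trimmed mean of M-values), carrying the scaling factors and
    library sizes used.

``FoldChangeTensor``
    per-gene, per-genotype log2 fold changes at each stress time relative
    to the genotype's own 0-h control, plus the 0-h baseline abundances.
    Fold changes live in a gene x (genotype, time) table with a two-level
    column index; missing values are ``NaN`` and always mean "flagged
    missing", never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PipelineError",
    "InputError",
    "ValidationError",
    "UsageError",
    "DegenerateInputError",
    "SampleAnnotation",
    "CountMatrix",
    "NormalizedMatrix",
    "FoldChangeTensor",
    "Thresholds",
]


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class InputError(PipelineError):
    """A required input file is missing or unreadable."""


class ValidationError(PipelineError):
    """An input violates a structural invariant (names the offender)."""


class UsageError(PipelineError):
    """An operation was called with inconsistent arguments."""


class DegenerateInputError(PipelineError):
    """Input is structurally valid but numerically degenerate."""


VALID_ASSAYS = ("mrna", "mirna")


@dataclass(frozen=True)
class SampleAnnotation:
    """One sequencing library: genotype, time point, replicate, assay."""

    sample_id: str
    genotype: str
    time_h: int
    replicate: int
    assay: str = "mrna"

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValidationError(f"sample {self.sample_id}: time_h must be >= 0")
        if self.replicate < 1:
            raise ValidationError(f"sample {self.sample_id}: replicate must be >= 1")
        if self.assay not in VALID_ASSAYS:
            raise ValidationError(
                f"sample {self.sample_id}: assay {self.assay!r} not in {VALID_ASSAYS}"
            )


def _samples_for(
    samples: Sequence[SampleAnnotation],
    genotype: str | None = None,
    time_h: int | None = None,
) -> list[SampleAnnotation]:
    hits = []
    for s in samples:
        if genotype is not None and s.genotype != genotype:
            continue
        if time_h is not None and s.time_h != time_h:
            continue
        hits.append(s)
    return hits


def _check_unique_design(samples: Sequence[SampleAnnotation]) -> None:
    seen: set[tuple] = set()
    ids: set[str] = set()
    for s in samples:
        key = (s.genotype, s.time_h, s.replicate, s.assay)
        if key in seen:
            raise ValidationError(f"duplicate design cell {key}")
        seen.add(key)
        if s.sample_id in ids:
            raise ValidationError(f"duplicate sample_id {s.sample_id!r}")
        ids.add(s.sample_id)


@dataclass
class CountMatrix:
    """Validated gene x sample matrix of non-negative integer read counts.

    ``counts`` is indexed by gene id with one column per sample, ordered
    as in ``samples``.
    """

    counts: pd.DataFrame
    samples: list[SampleAnnotation]

    def __post_init__(self) -> None:
        _check_unique_design(self.samples)
        sample_ids = [s.sample_id for s in self.samples]
        if list(self.counts.columns) != sample_ids:
            raise ValidationError("count columns do not match sample annotations")
        dup = self.counts.index[self.counts.index.duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate gene_id {dup[0]!r}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                bad = np.argwhere(~np.isfinite(values) | (values != np.floor(values)))
                g, s = bad[0]
                raise ValidationError(
                    f"non-integer count at gene {self.counts.index[g]!r}, "
                    f"sample {self.counts.columns[s]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if np.any(values < 0):
            bad = np.argwhere(values < 0)
            g, s = bad[0]
            raise ValidationError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def genotypes(self) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            if s.genotype not in out:
                out.append(s.genotype)
        return out

    def samples_for(
        self, genotype: str | None = None, time_h: int | None = None
    ) -> list[SampleAnnotation]:
        return _samples_for(self.samples, genotype, time_h)

    def subset_genes(self, genes: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)].copy(), list(self.samples))


@dataclass
class NormalizedMatrix:
    """TMM-scaled counts-per-million with the factors that produced them.

    Invariant: the geometric mean of ``factors`` is 1 (within 1e-9), so
    factors are comparable across runs.
    """

    values: pd.DataFrame
    samples: list[SampleAnnotation]
    factors: pd.Series
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        sample_ids = [s.sample_id for s in self.samples]
        if list(self.values.columns) != sample_ids:
            raise ValidationError("normalized columns do not match sample annotations")
        if np.any(self.factors.to_numpy() <= 0):
            raise ValidationError("TMM factors must be positive")
        log_gm = float(np.mean(np.log(self.factors.to_numpy())))
        if abs(log_gm) > 1e-9:
            raise ValidationError("TMM factors must have geometric mean 1")
        if np.any(self.values.to_numpy() < 0):
            raise ValidationError("normalized values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def samples_for(
        self, genotype: str | None = None, time_h: int | None = None
    ) -> list[SampleAnnotation]:
        return _samples_for(self.samples, genotype, time_h)


@dataclass
class FoldChangeTensor:
    """Per-gene, per-genotype temporal log2 fold changes plus 0-h baselines.

    ``fc`` has a (genotype, time_h) column MultiIndex; ``baseline`` has one
    column per genotype. NaN entries are flagged-missing.
    """

    fc: pd.DataFrame
    baseline: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.fc.columns, pd.MultiIndex):
            raise ValidationError("fc columns must be a (genotype, time_h) MultiIndex")
        times = self.stress_times_h
        if list(times) != sorted(set(times)) or any(t <= 0 for t in times):
            raise ValidationError("stress times must be strictly ascending positives")
        if list(self.baseline.columns) != self.genotypes:
            raise ValidationError("baseline genotypes do not match fc genotypes")
        base = self.baseline.to_numpy()
        if np.any(base[np.isfinite(base)] < 0):
            raise ValidationError("baselines must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.fc.index)

    @property
    def genotypes(self) -> list[str]:
        return list(self.fc.columns.get_level_values(0).unique())

    @property
    def stress_times_h(self) -> list[int]:
        return sorted({int(t) for t in self.fc.columns.get_level_values(1)})

    def profile(self, gene: str, genotype: str) -> np.ndarray:
        """The gene's fc vector over ascending stress times in one genotype."""
        block = self.fc.loc[gene, genotype]
        return block.reindex(self.stress_times_h).to_numpy(dtype=float)

    def genotype_block(self, genotype: str) -> pd.DataFrame:
        """gene x stress-time fc table for one genotype (ascending times)."""
        if genotype not in self.genotypes:
            raise UsageError(f"unknown genotype {genotype!r}")
        return self.fc[genotype].reindex(columns=self.stress_times_h)

    def subset_genes(self, genes: Iterable[str]) -> "FoldChangeTensor":
        genes = list(genes)
        missing = [g for g in genes if g not in self.fc.index]
        if missing:
            raise UsageError(f"genes absent from tensor: {missing[:5]}")
        return FoldChangeTensor(self.fc.loc[genes].copy(), self.baseline.loc[genes].copy())

    def to_long(self) -> pd.DataFrame:
        """Long-format table (gene, genotype, time_h, log2fc, baseline)."""
        rows = self.fc.stack([0, 1], future_stack=True).rename("log2fc").reset_index()
        rows.columns = ["gene", "genotype", "time_h", "log2fc"]
        base = self.baseline.stack(future_stack=True).rename("baseline").reset_index()
        base.columns = ["gene", "genotype", "baseline"]
        out = rows.merge(base, on=["gene", "genotype"], how="left")
        return out.sort_values(["gene", "genotype", "time_h"], kind="stable").reset_index(
            drop=True
        )

    @classmethod
    def from_long(cls, table: pd.DataFrame) -> "FoldChangeTensor":
        required = {"gene", "genotype", "time_h", "log2fc", "baseline"}
        if not required.issubset(table.columns):
            raise ValidationError(f"long fc table needs columns {sorted(required)}")
        fc = table.pivot_table(
            index="gene", columns=["genotype", "time_h"], values="log2fc", dropna=False
        )
        base = table.drop_duplicates(["gene", "genotype"]).pivot_table(
            index="gene", columns="genotype", values="baseline", dropna=False
        )
        genotypes = list(dict.fromkeys(table["genotype"]))
        times = sorted(table["time_h"].unique())
        fc = fc.reindex(columns=pd.MultiIndex.from_product([genotypes, times]))
        base = base.reindex(columns=genotypes)
        genes = list(dict.fromkeys(table["gene"]))
        return cls(fc.reindex(genes), base.reindex(genes))


@dataclass(frozen=True)
class Thresholds:
    """Tunable cutoffs, defaulting to the published constants.

    fc_threshold
        |log2-FC| above which a gene responds (2, i.e. four-fold).
    pcc_responsive / pcc_constitutive
        |r| edge cutoffs for the responsive (0.95) and constitutive (0.8)
        module networks.
    low_abundance_cutoff
        normalized abundance below which a gene counts as near-zero.
    outlier_cap
        |log2-FC| beyond which a value is treated as an extreme outlier.
    """

    fc_threshold: float = 2.0
    pcc_responsive: float = 0.95
    pcc_constitutive: float = 0.8
    low_abundance_cutoff: float = 1.0
    outlier_cap: float = 12.0

    def __post_init__(self) -> None:
        for name in (
            "fc_threshold",
            "pcc_responsive",
            "pcc_constitutive",
            "low_abundance_cutoff",
            "outlier_cap",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.pcc_responsive > 1 or self.pcc_constitutive > 1:
            raise ValidationError("correlation thresholds must be <= 1")
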