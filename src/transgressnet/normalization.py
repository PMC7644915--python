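"""Between-sample normalization and the temporal log2 fold-change tensor.

TMM (trimmed mean of M-values) corrects counts-per-million for library
*composition*: a handful of very abundant transcripts in one library
deflate the apparent expression of everything else, and a doubly-trimmed,
precision-weighted mean of per-gene log ratios against a reference sample
estimates that bias. The implementation follows the standard
Robinson-Oshlack procedure:

1. pick as reference the sample whose 75th-percentile count fraction is
   closest to the across-sample mean of those fractions (ties: lowest
   sample index);
2. for every other sample, over genes nonzero in both libraries, compute
   M = log2 of the ratio of count fractions and A = the average log2
   abundance;
3. discard the most extreme 30% of M values and 5% of A values (both
   tails, by rank);
4. the scaling factor is 2 to the mean of the surviving M values weighted
   by inverse asymptotic binomial variance;
5. rescale all factors to geometric mean 1.

Fold changes are computed per genotype against its own 0-h control:
replicates are averaged on the normalized scale first, then
fc = log2(stress mean + pseudocount) - log2(control mean + pseudocount).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import (
    CountMatrix,
    DegenerateInputError,
    FoldChangeTensor,
    NormalizedMatrix,
    UsageError,
)

__all__ = ["tmm_factors", "normalize", "low_abundance_mask", "fold_change_tensor"]


def _pairwise_tmm(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Scaling factor of one library against the reference (untrimmed
    genes only; returns the factor on the natural scale, not yet rescaled
    to geometric mean 1)."""
    keep = (obs > 0) & (ref > 0)
    if not np.any(keep):
        raise DegenerateInputError("no overlapping nonzero genes between sample pair")
    y, r = obs[keep].astype(float), ref[keep].astype(float)
    p_y, p_r = y / n_obs, r / n_ref
    m = np.log2(p_y / p_r)
    a = 0.5 * np.log2(p_y * p_r)
    # Asymptotic binomial variance of M; weights are its inverse.
    v = (n_obs - y) / (n_obs * y) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep2):
        return 1.0
    w = 1.0 / v[keep2]
    f = float(np.sum(m[keep2] * w) / np.sum(w))
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    matrix: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1."""
    counts = matrix.counts.to_numpy(dtype=float)
    n_genes, n_samples = counts.shape
    if n_samples < 2:
        raise UsageError("TMM requires at least 2 samples")
    lib = counts.sum(axis=0)
    if np.any(lib <= 0):
        sid = matrix.sample_ids[int(np.argmin(lib))]
        raise DegenerateInputError(f"sample {sid!r} has zero library size")
    f75 = np.array(
        [np.quantile(counts[:, s], 0.75) / lib[s] for s in range(n_samples)]
    )
    ref = int(np.argmin(np.abs(f75 - f75.mean())))  # argmin: lowest index on ties
    factors = np.ones(n_samples)
    for s in range(n_samples):
        if s == ref:
            continue
        try:
            factors[s] = _pairwise_tmm(
                counts[:, s], counts[:, ref], lib[s], lib[ref], trim_m, trim_a
            )
        except DegenerateInputError as exc:
            raise DegenerateInputError(
                f"{exc} (samples {matrix.sample_ids[s]!r}, {matrix.sample_ids[ref]!r})"
            ) from exc
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.sample_ids, name="tmm_factor")


def normalize(matrix: CountMatrix, factors: pd.Series | None = None) -> NormalizedMatrix:
    """TMM-scaled counts per million:
    value(g, s) = count(g, s) / (library_size(s) * factor(s)) * 1e6."""
    if factors is None:
        factors = tmm_factors(matrix)
    factors = factors.reindex(matrix.sample_ids)
    if factors.isna().any() or np.any(factors.to_numpy() <= 0):
        raise UsageError("need one positive factor per sample")
    lib = matrix.counts.sum(axis=0)
    if np.any(lib.to_numpy() <= 0):
        raise DegenerateInputError("zero library size")
    effective = lib.to_numpy(dtype=float) * factors.to_numpy(dtype=float)
    values = matrix.counts.to_numpy(dtype=float) / effective * 1e6
    return NormalizedMatrix(
        values=pd.DataFrame(values, index=matrix.counts.index, columns=matrix.counts.columns),
        samples=list(matrix.samples),
        factors=factors,
        library_sizes=lib.astype(np.int64),
    )


def low_abundance_mask(
    norm: NormalizedMatrix,
    cutoff: float = 1.0,
    min_samples: int = 2,
    sample_ids: list[str] | None = None,
) -> pd.Series:
    """True = keep: the gene reaches ``cutoff`` normalized units in at
    least ``min_samples`` samples (optionally restricted to a subset)."""
    if cutoff <= 0:
        raise UsageError("cutoff must be positive")
    values = norm.values if sample_ids is None else norm.values[sample_ids]
    keep = (values >= cutoff).sum(axis=1) >= min_samples
    keep.name = "keep"
    return keep


def fold_change_tensor(
    norm: NormalizedMatrix, pseudocount: float = 1.0, control_time_h: int = 0
) -> FoldChangeTensor:
    """Per-genotype temporal log2-FC against the 0-h control.

    Replicates are averaged on the normalized scale before the log
    transform; the pseudocount (default 1 normalized unit) keeps fold
    changes finite at zero abundance.
    """
    genotypes: list[str] = []
    for s in norm.samples:
        if s.genotype not in genotypes:
            genotypes.append(s.genotype)
    times = sorted({s.time_h for s in norm.samples if s.time_h != control_time_h})
    means: dict[tuple[str, int], np.ndarray] = {}
    for g in genotypes:
        ctrl = [s.sample_id for s in norm.samples_for(genotype=g, time_h=control_time_h)]
        if not ctrl:
            raise UsageError(f"genotype {g!r} lacks a {control_time_h} h control sample")
        means[(g, control_time_h)] = norm.values[ctrl].mean(axis=1).to_numpy()
        for t in times:
            reps = [s.sample_id for s in norm.samples_for(genotype=g, time_h=t)]
            if reps:
                means[(g, t)] = norm.values[reps].mean(axis=1).to_numpy()
    columns = pd.MultiIndex.from_tuples(
        [(g, t) for g in genotypes for t in times], names=["genotype", "time_h"]
    )
    fc = np.full((len(norm.gene_ids), len(columns)), np.nan)
    for j, (g, t) in enumerate(columns):
        if (g, t) not in means:
            continue
        fc[:, j] = np.log2(means[(g, t)] + pseudocount) - np.log2(
            means[(g, control_time_h)] + pseudocount
        )
    baseline = pd.DataFrame(
        {g: means[(g, control_time_h)] for g in genotypes}, index=norm.values.index
    )
    return FoldChangeTensor(
        fc=pd.DataFrame(fc, index=norm.values.index, columns=columns),
        baseline=baseline,
    )
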