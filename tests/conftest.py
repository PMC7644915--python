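"""Shared fixtures: hand-sized matrices and one default synthetic run.

The expensive artifacts (the default seed-42 synthetic dataset and the
pipeline outputs derived from it) are session-scoped so the recovery
tests and the acceptance suite share a single computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from transgressnet import (
    CountMatrix,
    SampleAnnotation,
    fold_change_tensor,
    normalize,
    tmm_factors,
)
from transgressnet.inheritance import trace_all
from transgressnet.mirna import collapse_families, pair_correlation
from transgressnet.modules import (
    refine_by_early_contrast,
    select_constitutive,
    select_steady_upregulated,
)
from transgressnet.network import (
    build_network,
    compare_networks,
    fragmentation_metrics,
    temporal_profiles,
)
from transgressnet.simulate import GeneratorConfig, SyntheticDataset, generate


def make_samples(
    genotypes=("A", "B"), times=(0, 24), replicates=1, assay="mrna"
) -> list[SampleAnnotation]:
    out = []
    for g in genotypes:
        for t in times:
            for r in range(1, replicates + 1):
                out.append(
                    SampleAnnotation(f"{g}_T{t:03d}_R{r}", g, t, r, assay)
                )
    return out


def random_count_matrix(
    rng: np.random.Generator,
    n_genes: int = 20,
    genotypes=("A", "B"),
    times=(0, 24),
    replicates=1,
) -> CountMatrix:
    samples = make_samples(genotypes, times, replicates)
    counts = rng.integers(0, 500, size=(n_genes, len(samples)))
    table = pd.DataFrame(
        counts,
        index=pd.Index([f"g{i:04d}" for i in range(n_genes)], name="gene_id"),
        columns=[s.sample_id for s in samples],
    )
    return CountMatrix(table, samples)


@pytest.fixture
def small_counts() -> CountMatrix:
    """3 genes x 4 samples (2 genotypes x 2 times), hand-written."""
    samples = make_samples(("A", "B"), (0, 24), replicates=1)
    table = pd.DataFrame(
        [[10, 20, 30, 40], [5, 5, 5, 5], [0, 100, 0, 100]],
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        columns=[s.sample_id for s in samples],
    )
    return CountMatrix(table, samples)


@dataclass
class PipelineRun:
    """All artifacts of one synthetic-data pipeline pass."""

    config: GeneratorConfig
    dataset: SyntheticDataset
    norm: object
    tensor: object
    trace: object
    steady: object
    refined: object
    constitutive: object
    module_reports: dict
    module_ranking: pd.DataFrame
    pair_table: pd.DataFrame


def run_pipeline(config: GeneratorConfig) -> PipelineRun:
    dataset = generate(config)
    norm = normalize(dataset.mrna, tmm_factors(dataset.mrna))
    tensor = fold_change_tensor(norm)
    trace = trace_all(
        tensor, norm, config.parent_a, config.parent_b, list(config.rils)
    )
    steady = select_steady_upregulated(tensor, config.focal)
    refined = refine_by_early_contrast(steady, tensor, list(config.inferior))
    constitutive = select_constitutive(
        tensor, config.focal, (config.parent_a, config.parent_b)
    )
    reports = {}
    for g in tensor.genotypes:
        profiles = temporal_profiles(tensor, dataset.truth.module_genes, g)
        net = build_network(profiles, 0.95, -0.95, genotype=g)
        reports[g] = fragmentation_metrics(net)
    ranking = compare_networks(list(reports.values()))
    fam_counts = collapse_families(dataset.mirna, dataset.family_map)
    fam_fc = fold_change_tensor(normalize(fam_counts))
    pair_table, _ = pair_correlation(fam_fc, tensor, dataset.pairs)
    return PipelineRun(
        config=config,
        dataset=dataset,
        norm=norm,
        tensor=tensor,
        trace=trace,
        steady=steady,
        refined=refined,
        constitutive=constitutive,
        module_reports=reports,
        module_ranking=ranking,
        pair_table=pair_table,
    )


@pytest.fixture(scope="session")
def default_run() -> PipelineRun:
    """Pipeline pass over the default study conditions (seed 42)."""
    return run_pipeline(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def noiseless_run() -> PipelineRun:
    """Same design with all noise terms off (Poisson limit)."""
    return run_pipeline(
        GeneratorConfig(seed=42, noise_sd=0.0, module_noise_sd=0.0, nb_dispersion=0.0)
    )
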