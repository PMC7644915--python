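"""Seeded synthetic-data generator with planted, recoverable structure.

The generator emulates the design of a two-parent / four-RIL salinity
time-course: 6 genotypes, samples at 0 (control), 24, 48, 72 and 144 h,
2 replicates, with parallel mRNA and miRNA libraries. It plants, on the
log2 scale:

* four inheritance classes (complete, parentA_like, parentB_like,
  non_parental) as discretized response templates copied between parents
  and RILs;
* a steadily-upregulated module in the focal genotype, with an early
  (24 h) downregulation contrast in the inferior genotypes;
* a constitutively-high module: raised 0-h baseline in the focal
  genotype with fold changes pinned inside the constant band;
* a co-expression module following a shared latent trajectory, whose
  per-genotype regime is coherent (one loading sign), fragmented (two
  sign-split blocks) or absent (independent noise);
* miRNA families with repressive targets whose fold-change profile
  mirrors the family's in the focal genotype.

Planted log2 means are exponentiated into expected counts and realized
as negative-binomial draws (Poisson when the dispersion is 0), so the
fold-change tensor the pipeline computes converges to the planted
templates as the noise terms vanish. Identical seeds yield byte-identical
outputs.

Planted responsive amplitudes sit ``amplitude_headroom`` log2 units
beyond threshold + margin (default |log2-FC| = 4, i.e. 16-fold).
Replicate-level counting noise at the default dispersion contributes an
irreducible ~0.45 log2 units of fold-change error, so the margin alone
would leave planted values within ~1.6 SD of the decision boundary; the
headroom keeps recovery limited by design, not by boundary effects,
while the configured margin remains the guaranteed minimum distance.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    write_count_matrix,
    write_sample_sheet,
)
from .mirna import write_family_map, write_pair_list
from .types import CountMatrix, SampleAnnotation, UsageError, ValidationError

__all__ = ["GeneratorConfig", "SyntheticTruth", "SyntheticDataset", "generate",
           "truth_report", "RecoveryReport", "write_dataset"]

INHERITANCE_CLASSES = ("complete", "parentA_like", "parentB_like", "non_parental")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design and noise parameters of the generator.

    Defaults mirror the emulated experiment: 6 genotypes (2 parents,
    4 RILs with a designated focal super-tolerant line and two inferior
    lines), stress times 24/48/72/144 h, 2 replicates, and published
    classification constants (fc threshold 2).
    """

    seed: int = 42
    parent_a: str = "IR29"
    parent_b: str = "Pokkali"
    rils: tuple[str, ...] = ("FL478", "FL454", "FL510", "FL499")
    focal: str = "FL510"
    inferior: tuple[str, ...] = ("FL454", "FL499")
    stress_times: tuple[int, ...] = (24, 48, 72, 144)
    n_replicates: int = 2
    n_per_class: int = 200
    steady_up_size: int = 40
    constitutive_size: int = 30
    coherent_module_size: int = 50
    fragmented_block_sizes: tuple[int, int] = (25, 25)
    module_regimes: Mapping[str, str] | None = None
    n_background: int = 150
    n_low_abundance: int = 20
    n_mirna_families: int = 12
    n_background_mirna_families: int = 24
    members_per_family: int = 4
    n_repressive_pairs: int = 10
    noise_sd: float = 0.25
    module_noise_sd: float = 0.05
    nb_dispersion: float = 0.1
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    planted_baseline_floor: float = 6.0
    fc_threshold: float = 2.0
    margin: float = 0.75
    amplitude_headroom: float = 1.25
    module_amplitude: float = 6.0
    module_direction: int = -1
    mirna_amplitude: float = 6.0
    depth_range: tuple[float, float] = (0.9, 1.1)

    @property
    def genotypes(self) -> tuple[str, ...]:
        return (self.parent_a, self.parent_b, *self.rils)

    @property
    def amplitude(self) -> float:
        """Planted responsive |log2-FC|: threshold + margin + headroom."""
        return self.fc_threshold + self.margin + self.amplitude_headroom

    def resolved_regimes(self) -> dict[str, str]:
        if self.module_regimes is not None:
            return dict(self.module_regimes)
        regimes = {}
        for g in self.genotypes:
            if g == self.focal:
                regimes[g] = "coherent"
            elif self.inferior and g == self.inferior[-1]:
                regimes[g] = "absent"
            else:
                regimes[g] = "fragmented"
        return regimes

    def validate(self) -> None:
        sizes = (
            self.n_per_class, self.steady_up_size, self.constitutive_size,
            self.coherent_module_size, self.n_background, self.n_low_abundance,
            self.n_mirna_families, self.members_per_family, self.n_repressive_pairs,
            self.n_replicates,
        )
        if any(s < 0 for s in sizes):
            raise ValidationError("all generator sizes must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("need at least 1 replicate")
        if self.noise_sd < 0 or self.module_noise_sd < 0 or self.nb_dispersion < 0:
            raise ValidationError("noise parameters must be >= 0")
        if self.margin < 0:
            raise ValidationError("margin must be >= 0")
        if sum(self.fragmented_block_sizes) != self.coherent_module_size:
            raise ValidationError("fragmented blocks must partition the module")
        if self.focal not in self.rils:
            raise ValidationError("focal genotype must be one of the RILs")
        if self.focal in self.inferior:
            raise ValidationError("focal genotype cannot be inferior")
        if self.n_repressive_pairs > self.n_mirna_families:
            raise ValidationError(
                "cannot plant more repressive pairs than miRNA families"
            )
        regimes = self.resolved_regimes()
        bad = {g: r for g, r in regimes.items()
               if r not in ("coherent", "fragmented", "absent")}
        if bad:
            raise ValidationError(f"unknown module regimes: {bad}")


@dataclass
class SyntheticTruth:
    """Planted structure, keyed by generated ids."""

    inheritance_class: dict[str, str]
    steady_up_genes: list[str]
    constitutive_genes: list[str]
    module_genes: list[str]
    fragmented_blocks: tuple[list[str], list[str]]
    module_regimes: dict[str, str]
    repressive_pairs: list[tuple[str, str]]
    low_abundance_genes: list[str]
    config: GeneratorConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "inheritance_class": self.inheritance_class,
            "steady_up_genes": self.steady_up_genes,
            "constitutive_genes": self.constitutive_genes,
            "module_genes": self.module_genes,
            "fragmented_blocks": [list(b) for b in self.fragmented_blocks],
            "module_regimes": self.module_regimes,
            "repressive_pairs": [list(p) for p in self.repressive_pairs],
            "low_abundance_genes": self.low_abundance_genes,
            "config": asdict(self.config),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        cfg = payload["config"]
        for key in ("rils", "inferior", "stress_times", "fragmented_block_sizes",
                    "depth_range"):
            cfg[key] = tuple(cfg[key])
        return cls(
            inheritance_class=payload["inheritance_class"],
            steady_up_genes=payload["steady_up_genes"],
            constitutive_genes=payload["constitutive_genes"],
            module_genes=payload["module_genes"],
            fragmented_blocks=(
                payload["fragmented_blocks"][0], payload["fragmented_blocks"][1]
            ),
            module_regimes=payload["module_regimes"],
            repressive_pairs=[tuple(p) for p in payload["repressive_pairs"]],
            low_abundance_genes=payload["low_abundance_genes"],
            config=GeneratorConfig(**cfg),
        )


@dataclass
class SyntheticDataset:
    mrna: CountMatrix
    mirna: CountMatrix
    samples: list[SampleAnnotation]
    family_map: dict[str, str]
    pairs: list[tuple[str, str]]
    truth: SyntheticTruth


def _ramp(times: Sequence[int]) -> np.ndarray:
    """Monotone latent trajectory scaled to max 1 over the stress times."""
    n = len(times)
    return np.arange(1, n + 1, dtype=float) / n


def _draw_pattern(rng: np.random.Generator, n_times: int,
                  forbidden: tuple[tuple[int, ...], ...] = ()) -> tuple[int, ...]:
    """A per-time code pattern in {-1,0,+1}^T.

    The all-up pattern is never drawn (it would collide with the
    steadily-upregulated module definition), nor any explicitly
    forbidden pattern.
    """
    all_up = tuple([1] * n_times)
    while True:
        p = tuple(int(c) for c in rng.integers(-1, 2, size=n_times))
        if p == all_up or p in forbidden:
            continue
        return p


def _realize_counts(rng: np.random.Generator, expected: np.ndarray,
                    dispersion: float) -> np.ndarray:
    expected = np.maximum(expected, 1e-8)
    if dispersion <= 0:
        return rng.poisson(expected)
    r = 1.0 / dispersion
    p = r / (r + expected)
    return rng.negative_binomial(r, p)


def generate(config: GeneratorConfig = GeneratorConfig()) -> SyntheticDataset:
    """Build the full synthetic dataset plus its machine-readable truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genotypes = list(config.genotypes)
    times = list(config.stress_times)
    n_t = len(times)
    amp = config.amplitude

    gene_ids: list[str] = []
    baselines: list[np.ndarray] = []  # per gene: per-genotype baseline log2 mean
    fc_templates: list[np.ndarray] = []  # per gene: genotype x time planted log2-FC
    truth_class: dict[str, str] = {}

    def new_gene(prefix: str, idx: int) -> str:
        gid = f"{prefix}{idx:05d}"
        gene_ids.append(gid)
        return gid

    def planted_baseline() -> float:
        b = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd)
        return float(max(b, config.planted_baseline_floor))

    gi = 0

    # --- inheritance classes -------------------------------------------------
    ril_index = {r: genotypes.index(r) for r in config.rils}
    ia, ib = genotypes.index(config.parent_a), genotypes.index(config.parent_b)
    for cls in INHERITANCE_CLASSES:
        for _ in range(config.n_per_class):
            gid = new_gene("g", gi); gi += 1
            truth_class[gid] = cls
            if cls == "complete":
                pa = pb = pr = _draw_pattern(rng, n_t)
            elif cls == "parentA_like":
                pa = _draw_pattern(rng, n_t)
                pb = _draw_pattern(rng, n_t, forbidden=(pa,))
                pr = pa
            elif cls == "parentB_like":
                pa = _draw_pattern(rng, n_t)
                pb = _draw_pattern(rng, n_t, forbidden=(pa,))
                pr = pb
            else:  # non_parental
                pa = _draw_pattern(rng, n_t)
                pb = _draw_pattern(rng, n_t)
                pr = _draw_pattern(rng, n_t, forbidden=(pa, pb))
            tmpl = np.zeros((len(genotypes), n_t))
            tmpl[ia] = np.array(pa, dtype=float) * amp
            tmpl[ib] = np.array(pb, dtype=float) * amp
            for r in config.rils:
                tmpl[ril_index[r]] = np.array(pr, dtype=float) * amp
            tmpl += rng.normal(0.0, config.noise_sd, size=tmpl.shape)
            fc_templates.append(tmpl)
            b = planted_baseline()
            baselines.append(np.full(len(genotypes), b))

    # --- steadily-upregulated module ----------------------------------------
    steady_genes: list[str] = []
    fi = genotypes.index(config.focal)
    late = [t >= times[-2] for t in times]  # delayed induction elsewhere
    for _ in range(config.steady_up_size):
        gid = new_gene("g", gi); gi += 1
        steady_genes.append(gid)
        tmpl = rng.normal(0.0, config.noise_sd, size=(len(genotypes), n_t))
        tmpl[fi] = amp + np.abs(rng.normal(0.0, config.noise_sd, size=n_t))
        for g in config.inferior:
            tmpl[genotypes.index(g), 0] = -amp + rng.normal(0.0, config.noise_sd)
        for g in (config.parent_a, config.parent_b):
            gidx = genotypes.index(g)
            for j, is_late in enumerate(late):
                if is_late:
                    tmpl[gidx, j] = amp + rng.normal(0.0, config.noise_sd)
        fc_templates.append(tmpl)
        baselines.append(np.full(len(genotypes), planted_baseline()))

    # --- constitutively-high module ------------------------------------------
    constitutive_genes: list[str] = []
    stability_clip = max(config.fc_threshold - config.margin, 0.0)
    for _ in range(config.constitutive_size):
        gid = new_gene("g", gi); gi += 1
        constitutive_genes.append(gid)
        tmpl = np.zeros((len(genotypes), n_t))
        for gidx, g in enumerate(genotypes):
            if g == config.focal:
                tmpl[gidx] = np.clip(
                    rng.normal(0.0, config.noise_sd, size=n_t),
                    -stability_clip, stability_clip,
                )
            else:
                pat = np.array(_draw_pattern(rng, n_t), dtype=float)
                tmpl[gidx] = pat * amp + rng.normal(0.0, config.noise_sd, size=n_t)
        fc_templates.append(tmpl)
        b = planted_baseline()
        base = np.full(len(genotypes), b)
        base[fi] = b + amp  # raised focal baseline, >= base_threshold + margin
        baselines.append(base)

    # --- co-expression module -------------------------------------------------
    module_genes: list[str] = []
    regimes = config.resolved_regimes()
    lam = config.module_direction * config.module_amplitude * _ramp(times)
    loadings = rng.uniform(0.8, 1.2, size=config.coherent_module_size)
    block_signs = np.ones(config.coherent_module_size)
    block_signs[config.fragmented_block_sizes[0]:] = -1.0
    for k in range(config.coherent_module_size):
        gid = new_gene("g", gi); gi += 1
        module_genes.append(gid)
        tmpl = np.zeros((len(genotypes), n_t))
        for gidx, g in enumerate(genotypes):
            regime = regimes[g]
            if regime == "coherent":
                tmpl[gidx] = loadings[k] * lam
            elif regime == "fragmented":
                tmpl[gidx] = block_signs[k] * loadings[k] * lam
            else:  # absent: independent noise only
                tmpl[gidx] = rng.normal(0.0, config.noise_sd, size=n_t)
            tmpl[gidx] += rng.normal(0.0, config.module_noise_sd, size=n_t)
        fc_templates.append(tmpl)
        baselines.append(np.full(len(genotypes), planted_baseline()))
    blocks = (
        module_genes[: config.fragmented_block_sizes[0]],
        module_genes[config.fragmented_block_sizes[0]:],
    )

    # --- background and near-zero genes ---------------------------------------
    low_abundance_genes: list[str] = []
    for _ in range(config.n_background):
        new_gene("g", gi); gi += 1
        fc_templates.append(rng.normal(0.0, config.noise_sd, size=(len(genotypes), n_t)))
        b = float(rng.normal(config.baseline_log2_mean, config.baseline_log2_sd))
        baselines.append(np.full(len(genotypes), b))
    for _ in range(config.n_low_abundance):
        gid = new_gene("g", gi); gi += 1
        low_abundance_genes.append(gid)
        fc_templates.append(np.zeros((len(genotypes), n_t)))
        baselines.append(np.full(len(genotypes), float(rng.normal(-6.0, 0.5))))

    # --- miRNA families, members and repressive targets -----------------------
    # A stable background of families anchors the miRNA normalization,
    # as the bulk of a real miRNA library does; without it the planted
    # shifts dominate library composition and TMM absorbs the signal.
    family_ids = [f"miR{900 + i}" for i in range(config.n_mirna_families)]
    background_family_ids = [
        f"miR{500 + i}" for i in range(config.n_background_mirna_families)
    ]
    family_fc: dict[str, np.ndarray] = {}
    family_base: dict[str, float] = {}
    mir_ramp = config.mirna_amplitude * _ramp(times)
    pairs: list[tuple[str, str]] = []
    target_templates: list[tuple[str, np.ndarray, float]] = []
    for i, fam in enumerate(family_ids):
        tmpl = np.zeros((len(genotypes), n_t))
        repressive = i < config.n_repressive_pairs
        # Repressive families are planted as sustained focal upregulation,
        # so their mirrored targets are downregulated there and cannot
        # collide with the steadily-upregulated module rule.
        a_f = float(rng.uniform(0.8, 1.2))
        for gidx, g in enumerate(genotypes):
            if g == config.focal:
                if repressive:
                    tmpl[gidx] = a_f * mir_ramp
                else:
                    tmpl[gidx] = rng.normal(0.0, config.noise_sd, size=n_t)
            else:
                pat = np.array(_draw_pattern(rng, n_t), dtype=float)
                tmpl[gidx] = pat * amp + rng.normal(0.0, config.noise_sd, size=n_t)
        family_fc[fam] = tmpl
        family_base[fam] = float(
            max(rng.normal(config.baseline_log2_mean + 1.0, 1.0),
                config.planted_baseline_floor)
        )
        if repressive:
            tgt = f"t{i:03d}"
            pairs.append((fam, tgt))
            t_tmpl = rng.normal(0.0, config.noise_sd, size=(len(genotypes), n_t))
            t_tmpl[fi] = -tmpl[fi] + rng.normal(
                0.0, config.module_noise_sd, size=n_t
            )
            target_templates.append((tgt, t_tmpl, planted_baseline()))
    for tgt, t_tmpl, b in target_templates:
        gene_ids.append(tgt)
        fc_templates.append(t_tmpl)
        baselines.append(np.full(len(genotypes), b))
    for fam in background_family_ids:
        family_fc[fam] = rng.normal(
            0.0, config.noise_sd, size=(len(genotypes), n_t)
        )
        family_base[fam] = float(
            max(rng.normal(config.baseline_log2_mean + 1.0, 1.0),
                config.planted_baseline_floor)
        )

    family_map: dict[str, str] = {}
    mir_ids: list[str] = []
    mir_templates: list[np.ndarray] = []
    mir_baselines: list[np.ndarray] = []
    for fam in family_ids + background_family_ids:
        for m in range(config.members_per_family):
            mid = f"{fam}{chr(ord('a') + m)}"
            family_map[mid] = fam
            mir_ids.append(mid)
            member_fc = family_fc[fam] + rng.normal(
                0.0, config.module_noise_sd, size=family_fc[fam].shape
            )
            mir_templates.append(member_fc)
            b = family_base[fam] - np.log2(config.members_per_family) + float(
                rng.normal(0.0, 0.3)
            )
            mir_baselines.append(np.full(len(genotypes), b))

    # --- realize counts --------------------------------------------------------
    def make_samples(assay: str) -> list[SampleAnnotation]:
        out = []
        suffix = "" if assay == "mrna" else "m"
        for g, t, rep in product(genotypes, [0, *times], range(1, config.n_replicates + 1)):
            out.append(
                SampleAnnotation(
                    sample_id=f"{g}_T{t:03d}_R{rep}{suffix}",
                    genotype=g, time_h=t, replicate=rep, assay=assay,
                )
            )
        return out

    def realize(ids: list[str], base: list[np.ndarray], tmpl: list[np.ndarray],
                samples: list[SampleAnnotation]) -> CountMatrix:
        depths = rng.uniform(*config.depth_range, size=len(samples))
        log2_mean = np.empty((len(ids), len(samples)))
        for j, s in enumerate(samples):
            gidx = genotypes.index(s.genotype)
            if s.time_h == 0:
                fc_col = np.zeros(len(ids))
            else:
                tidx = times.index(s.time_h)
                fc_col = np.array([tmpl[i][gidx, tidx] for i in range(len(ids))])
            log2_mean[:, j] = (
                np.array([base[i][gidx] for i in range(len(ids))]) + fc_col
            )
        expected = np.exp2(log2_mean) * depths[None, :]
        counts = _realize_counts(rng, expected, config.nb_dispersion)
        table = pd.DataFrame(counts, index=pd.Index(ids, name="gene_id"),
                             columns=[s.sample_id for s in samples])
        return CountMatrix(table, samples)

    mrna_samples = make_samples("mrna")
    mirna_samples = make_samples("mirna")
    mrna = realize(gene_ids, baselines, fc_templates, mrna_samples)
    mirna = realize(mir_ids, mir_baselines, mir_templates, mirna_samples)

    truth = SyntheticTruth(
        inheritance_class=truth_class,
        steady_up_genes=steady_genes,
        constitutive_genes=constitutive_genes,
        module_genes=module_genes,
        fragmented_blocks=blocks,
        module_regimes=regimes,
        repressive_pairs=pairs,
        low_abundance_genes=low_abundance_genes,
        config=config,
    )
    return SyntheticDataset(
        mrna=mrna,
        mirna=mirna,
        samples=[*mrna_samples, *mirna_samples],
        family_map=family_map,
        pairs=pairs,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write all generated TSVs plus truth.json; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mrna_counts": out / "mrna_counts.tsv",
        "mirna_counts": out / "mirna_counts.tsv",
        "samples": out / "samples.tsv",
        "family_map": out / "family_map.tsv",
        "pairs": out / "mirna_targets.tsv",
        "truth": out / "truth.json",
    }
    write_count_matrix(dataset.mrna, paths["mrna_counts"])
    write_count_matrix(dataset.mirna, paths["mirna_counts"])
    write_sample_sheet(dataset.samples, paths["samples"])
    write_family_map(dataset.family_map, paths["family_map"])
    write_pair_list(dataset.pairs, paths["pairs"])
    dataset.truth.to_json(paths["truth"])
    return paths


@dataclass
class RecoveryReport:
    """How well the pipeline recovered the planted structure (all
    metrics in [0, 1], plus the inheritance confusion matrix)."""

    metrics: dict[str, float]
    confusion: pd.DataFrame


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def truth_report(
    truth: SyntheticTruth,
    trace_calls: pd.DataFrame | None = None,
    steady_module=None,
    constitutive_module=None,
    network_ranking: pd.DataFrame | None = None,
    pair_table: pd.DataFrame | None = None,
) -> RecoveryReport:
    """Recovery metrics for whichever pipeline outputs are supplied."""
    metrics: dict[str, float] = {}
    confusion = pd.DataFrame()
    if trace_calls is not None:
        planted = truth.inheritance_class
        subset = trace_calls[trace_calls["gene"].isin(planted)].copy()
        if subset.empty:
            raise UsageError("trace calls share no gene ids with the truth")
        subset["truth"] = subset["gene"].map(planted)
        metrics["inheritance_accuracy"] = float(
            (subset["category"] == subset["truth"]).mean()
        )
        confusion = pd.crosstab(subset["truth"], subset["category"])
        for cls in INHERITANCE_CLASSES:
            cls_rows = subset[subset["truth"] == cls]
            metrics[f"accuracy_{cls}"] = float(
                (cls_rows["category"] == cls).mean()
            ) if len(cls_rows) else float("nan")
    if steady_module is not None:
        metrics["steady_up_jaccard"] = _jaccard(
            set(steady_module.members), set(truth.steady_up_genes)
        )
    if constitutive_module is not None:
        metrics["constitutive_jaccard"] = _jaccard(
            set(constitutive_module.members), set(truth.constitutive_genes)
        )
    if network_ranking is not None:
        coherent = [g for g, r in truth.module_regimes.items() if r == "coherent"]
        if coherent:
            top = network_ranking.iloc[0]["genotype"]
            metrics["regime_ranking_correct"] = float(top in coherent)
    if pair_table is not None:
        focal = truth.config.focal
        flagged = pair_table[
            (pair_table["genotype"] == focal) & pair_table["repression_consistent"]
        ]
        found = {(r.family, r.gene) for r in flagged.itertuples(index=False)}
        planted_pairs = set(map(tuple, truth.repressive_pairs))
        if planted_pairs and not set(pair_table["family"]) & {
            p[0] for p in planted_pairs
        }:
            raise UsageError("pair table shares no families with the truth")
        metrics["pair_recall"] = (
            len(found & planted_pairs) / len(planted_pairs) if planted_pairs else 1.0
        )
    return RecoveryReport(metrics=metrics, confusion=confusion)
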