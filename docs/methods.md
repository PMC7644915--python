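# Methods

This note records the statistical procedures, the parameters that
matter, the design choices made where more than one reading was
defensible, and what the synthetic-data experiments do and do not show.

## Pipeline model

The pipeline treats a stress time course over a panel of genotypes
(parents and RILs) as a gene × genotype × time tensor of log2 fold
changes relative to each genotype's own 0-h control. All downstream
analyses — response classification, inheritance tracing, module
selection, co-expression networks, miRNA integration — are deterministic
functions of that tensor (plus 0-h baselines), so the tensor is the
single interchange object (`FoldChangeTensor`, also serialized as a
long-format TSV).

### Normalization

Between-sample scaling uses the trimmed mean of M-values. The reference
sample is the one whose 75th-percentile count fraction is closest to the
panel mean (ties broken by lowest sample index, for determinism). For
each other sample, per-gene log ratios M and average abundances A are
computed over genes nonzero in both libraries; the most extreme 30 % of
M and 5 % of A are discarded (both tails, by rank), and the factor is
2 to the inverse-variance-weighted mean of the surviving M values, using
the asymptotic binomial variance (N−y)/(Ny) + (N_r−r)/(N_r r). Factors
are rescaled to geometric mean 1 so they are comparable across runs.
The implementation reproduces Bioconductor edgeR's `calcNormFactors`
to ≈1e-12 on random fixtures (one test runs the comparison through
Rscript).

Normalized abundance is CPM on the effective library
(library size × factor). Fold changes average replicates on the
normalized scale *before* the log transform (mean-then-log), with a
pseudocount of 1 normalized unit so zeros stay finite; 1 CPM-equivalent
is the conventional choice and the smallest value that does not distort
moderately expressed genes.

### Classification and inheritance

Response calls use strict inequalities at the ±2 log2 threshold
(a fold change of exactly 2.0 is constant). The up and down flags are
independent; a "mixed" category preserves genes crossing both bounds, so
panel-style counts are recoverable as up = up_only + mixed.

"Same expression pattern as a parent" is operationalized as identical
per-time discretized codes at the same ±2 granularity — the least
arbitrary choice given that the classification threshold is the only
published granularity; a continuous alternative (Chebyshev distance on
the raw fold-change vectors, configurable δ) is available via
`match_mode="chebyshev"`. Baseline similarity is *not* part of the
default match: the categories describe response *patterns*. Genes are
excluded per trio (RIL + both parents) before matching: `low_abundance`
when the gene never reaches 1 CPM in ≥2 of the trio's samples,
`outlier` when any |log2FC| in the trio exceeds the cap (default 12
log2 units, a concrete stand-in for "extremely outlying values").

### Module selection

Two published ambiguities are exposed as options rather than hidden in
constants:

* "downregulated in the inferior genotypes at 24 h" defaults to
  `lenient` (fc < 0) with a `strict` variant (fc ≤ −2);
* the constitutive baseline contrast defaults to "> 2 log2 units above
  the parental *mean*", with a per-parent variant (`both_parents`)
  that provably selects a subset of the mean-rule set.

Stability of the constitutive module reuses the strict |fc| < 2 band.

### Networks

Profiles are the per-genotype fold-change vectors, prefixed by default
with the control point (identically 0), lengthening 4-point profiles to
5; correlations over 4 points are extremely coarse and the control
point is definitionally part of the trajectory. The 4-point variant is
available (`include_control_zero=False`). Edge thresholds are
inclusive ("at least" 0.95, or 0.8 for the constitutive module). No
p-values are attached — at n = 5 they would be decorative — matching
the thresholding-only design.

Fragmentation metrics: connected components of the full graph and of
the positive-edge subgraph, largest positive component fraction,
degree-0 ("straggler") nodes, negative-edge fraction, and degrees of
caller-supplied hub genes. An edgeless graph has largest-component
fraction 1/n (each node its own component): no special case, and the
metric stays monotone with cohesion. Genotypes are ranked by largest
positive component fraction (descending), ties by negative-edge
fraction (ascending), with a stable sort.

### miRNA integration

Families are collapsed by summing member counts (abundance semantics;
a mean mode exists because figure-style summaries often average), then
normalized and fold-changed like mRNA. Spread statistics per genotype
are min, max, IQR (linear-interpolation quartiles) and SD (n−1
denominator) of the pooled family × time fold changes. The
repression screen correlates each family profile with each supplied
target profile per genotype and flags r ≤ −0.8, reusing the relaxed
constitutive network threshold since no dedicated constant exists.

## Synthetic data: what is planted and why

The generator emulates the motivating design: 6 genotypes (2 parents,
4 RILs with a designated focal line and two inferior lines), times
0/24/48/72/144 h, 2 replicates, parallel mRNA and miRNA libraries.
Defaults: 200 genes per inheritance class, 40 steady-up genes, 30
constitutive genes, a 50-gene co-expression module (25+25 fragmented
blocks), 12 miRNA families of 4 members with 10 repressive targets,
template noise sd 0.25 log2 units, module noise sd 0.05, NB dispersion
0.1, baseline log2-CPM ~ N(8, 1.5) with planted genes floored at 6.

Counts are negative binomial around 2^(baseline + planted fc) with a
per-sample depth factor in [0.9, 1.1]; dispersion 0 degenerates to
Poisson. Because structure is planted on the log scale and
exponentiated, the computed tensor converges to the planted templates
as the noise terms vanish; with all noise off, recovery of every
class, module, regime and pair is exact (tested).

Three deliberate design choices:

* **Amplitude headroom.** With dispersion 0.1 and 2 replicates, each
  computed fold change carries an irreducible ≈0.45 log2 sd of
  counting noise (CV² ≈ φ per replicate, halved by averaging, doubled
  across the two log terms). Responsive values planted exactly at
  threshold + margin = 2.75 would sit ~1.6 sd from the decision
  boundary and misclassify far too often for the intended ≥95 %
  recovery. Planted amplitudes therefore default to
  threshold + margin + 1.25 = 4 log2 units (16-fold, typical of
  strongly stress-responsive genes); the margin remains the guaranteed
  *minimum* distance from any decision boundary.
* **Disjoint planted memberships.** Inheritance templates never draw
  the all-up pattern, and repressive miRNA families are planted as
  focal *up*-regulation (so their mirrored targets are down). Both
  rules prevent planted genes from accidentally satisfying the
  steady-up module definition, keeping module truth identifiable.
* **Stable miRNA background.** 24 flat background families accompany
  the 12 planted ones. Without them the planted shifts dominate the
  tiny miRNA library's composition and TMM absorbs the signal itself
  (the same pathology as normalizing a panel where most genes are DE);
  real miRNA libraries have exactly such a stable bulk.

The latent module trajectory is a monotone ramp (scaled 0.25…1 of the
module amplitude, default 6, planted as coordinated *down*-regulation),
so 5-point profiles always have nonzero variance; fragmented regimes
flip the sign of the second block; absent regimes use independent
noise.

### What the synthetic experiments do not show

The generator plants clean template structure: discrete inheritance
patterns shared by all RILs of a class, block-structured modules, and a
single latent trajectory per module. Real data have correlated
replicates, batch effects, partially overlapping modules,
genotype-specific dispersions and ambiguous intermediate patterns.
Passing recovery tests therefore demonstrates that the *operations*
implement their definitions and are robust to counting noise at
realistic dispersion — not that the biological conclusions of any
particular dataset are reproduced. Headline gene counts from the
motivating study (e.g., module sizes of a few hundred genes) depend on
read processing and unstated filtering choices and are out of scope.

## Numerical conventions

* Missing fold changes are NaN end to end, serialized as `NA`, and
  never conflated with 0.
* Correlations are clipped into [−1, 1]; zero-variance profiles yield
  missing r and never an edge.
* Edge lists are written sorted with r at 12 decimals; GraphML node and
  edge order is fixed — outputs are byte-stable for identical inputs,
  and the run report embeds SHA-256 checksums of every output.
* All randomness flows from one `numpy` Generator seeded by the
  configuration; identical seeds give byte-identical datasets.

## Problem sizes used in validation

The default validation dataset is 1,100 mRNA genes (800 inheritance,
40 + 30 module, 50 co-expression, 150 background, 20 near-zero, 10
miRNA targets) and 144 miRNAs across 60 + 60 libraries; a full pipeline
pass takes about 1.5 s, and the whole test suite runs in well under a
minute. Sizes were chosen so that every planted class has enough
members for stable recovery fractions while keeping iteration fast.
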