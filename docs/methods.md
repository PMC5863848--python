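# Methods

## Scope and data model

`triohet` analyses a *trio*: a female parent, a male parent and their F1
hybrid, each with one or more gene-level RNA-seq count libraries. The
motivating design is a single library per genotype, which shapes two
choices below (blind dispersion pooling, and a classifier built on
pairwise calls rather than a joint model). Counts arrive as a TSV whose
header encodes `sample:genotype:replicate`, so genotype roles travel with
the matrix.

## Quantification

FPKM(g, s) = count(g, s)·10⁹ / (length(g)·total(s)) with total(s) the
column sum of the supplied matrix. Upstream effective-length and
multi-mapping corrections are deliberately out of scope: starting from a
count matrix keeps the arithmetic self-contained and exactly testable
(per sample, Σ_g FPKM·length = 10⁹). The analysis universe is genes with
FPKM strictly greater than 1 in at least one sample; the strict
inequality and the threshold are both configurable (`fpkm_min`).

## Differential expression

* **Normalization** — median-of-ratios size factors: factor(s) = median
  over genes with all-positive counts of count(g, s)/geomean_g. When no
  gene is positive everywhere, an explicit `allow_pseudo_reference` flag
  switches the geometric means to positive entries only; silent fallback
  seemed worse than an actionable error.
* **Model** — NB with variance μ + αμ²; α = 0 degenerates to Poisson.
* **Dispersion** — method of moments on normalized counts:
  α̂ = (v − m·mean(1/s))/m², clipped at 0. `blind_pooled` (default, and
  the only honest option at one library per genotype) pools all samples
  regardless of genotype, which over-estimates α for genes that truly
  differ between genotypes — conservative in the direction that matters.
  `per_group` pools within the two contrast groups (needs ≥ 2 replicates
  each). Either raw estimate is shrunk toward the across-gene median
  with weight 0.5; the moment estimator at n = 3–5 is far too noisy to
  use unshrunk, and with homogeneous simulated dispersions the median is
  close to the truth. `fixed:<α>` bypasses estimation.
* **Test** — Wald statistic on log(μ̂₂+ε) − log(μ̂₁+ε) with delta-method
  variance (1/n²)Σ_j(1/((μ̂+ε)s_j) + α) per group and a normal reference,
  ε = 0.5. A Student-t reference with df = n₁+n₂−2 was evaluated and
  rejected: it overcorrects (empirical type-I ≈ 0.015–0.02 at nominal
  0.05 with n = 3), while the normal reference stays mildly
  anticonservative (0.06–0.09) — inside the band we consider acceptable
  for a moment-based small-sample test, and the BH layer absorbs most of
  it. In the Poisson single-library case the statistic tracks the exact
  conditional binomial test to |Δp| ≤ 0.02 at moderate counts, which the
  suite verifies.
* **Calls** — up/down/ns from significance ≤ α (BH q by default, raw p
  behind a flag) and |log2FC| ≥ log2(min_fold); DEG reporting defaults
  to α = 0.05, min_fold = 2.

## Pattern classification

Each gene's three calls (parents; F1 vs female; F1 vs male) index a
27-cell decision table. Exactly 13 cells are logically consistent with
some ordering of three expression levels — 12 patterns plus all-ns — and
the remaining 14 cells are NC by construction, never forced into a
pattern. The correspondence of overdominance sub-indices to parental
direction (P7 female-higher, P8 male-higher, P9 parents-equal, and
mirrored P10–P12) is a documented package convention; the rollup classes
(P1–P2 additive, P3–P4 HPD, P5–P6 LPD, P7–P9 UOD, P10–P12 DOD) do not
depend on it.

Two deliberate differences between pattern calls and DEG reporting:

1. **No fold-change filter for pattern calls** (min_fold = 1). An F1 at
   the arithmetic mid-parent satisfies F1/HP = (1+r)/(2r) ≥ ½ for any
   parental ratio r, so a ≥ 2-fold requirement on the F1-vs-high-parent
   comparison would make the additive patterns unreachable in principle.
   The fold filter is a reporting convention for DEG sets, not part of
   the inheritance-mode taxonomy.
2. **BH-adjusted calls by default.** Measured on planted simulations
   (2000 genes, 5 replicates, 4-fold effects, dispersion 0.05, six
   seeds), q-based calls recover 96–97% of planted patterns and
   96.5–97.5% of rollup classes versus 93–95.5% / 93.5–96% for raw-p
   calls: the adjustment suppresses the false near-parent calls that
   break dominance rollups, while the strong true contrasts keep their
   significance. Raw-p mode remains available (`pattern_use_adjusted`).

## Heterosis indices

HP/LP are assigned per measurement cell (a parent may switch rank across
years or stages). BPH is reported as the signed low-parent index — an F1
above the low parent gives a positive value. `mph_from_oph_bph`
implements the exact harmonic-mean identity; feeding it *printed*
two-decimal OPH/BPH propagates up to ~0.005 of input rounding into the
implied MPH, so published-table audits compare at ±0.01 and, rigorously,
check that the printed MPH lies in the interval attainable from the
printed-precision inputs. Per-gene indices are computed on genotype-mean
FPKM; genes with a zero parental mean are flagged (`ok=False`) rather
than dropped, since a percent deviation from zero is undefined.

## Enrichment

Upper-tail hypergeometric p per term, BH across tested terms. The
population defaults to the FPKM-filtered universe, not the whole
annotation — testing against genes that could never have been detected
biases every term toward significance. Terms with fewer than two members
in the population are excluded as untestable. Over-representation only;
depletion is not tested.

## qPCR

2^-ΔΔCt with amplification efficiency fixed at 2 and a single reference
gene (Actin-2 by default); technical replicates are averaged on the Ct
scale (Livak's usage), with a geometric-mean-of-folds alternative behind
a flag (identical for balanced replicates). Concordance is an OLS fit of
qPCR on RNA-seq log2 fold changes; R² is the squared Pearson
correlation, invariant to affine rescaling of either axis.

## Synthetic data

The generator emulates the *structure* of a parent/hybrid transcriptome
comparison, not any particular dataset:

* **Baseline expression** — per-gene lognormal mean counts,
  meanlog = 5.5, sdlog = 0.8 (median ≈ 245): well-expressed genes of the
  kind that survive the FPKM filter in a deep bulk library.
* **Class mixture** — null 0.54; HPD 0.14 and LPD 0.13 with a paternal
  excess (hpd_m 0.09/hpd_f 0.05, lpd_m 0.08/lpd_f 0.05); UOD 0.09;
  DOD 0.06; additive 0.04. Dominance-heavy, paternal-dominance-largest,
  additivity rare — the qualitative structure reported for tobacco
  parent/hybrid comparisons.
* **Planted means** — parents differing classes separate the parents by
  `effect_size_log2` (default 2, i.e. 4-fold); additive F1 sits at the
  arithmetic mid-parent; dominant F1 at one parent; overdominant F1 one
  further effect-multiple beyond the high (or below the low) parent.
  Overdominant classes cycle deterministically through their three
  parental sub-patterns.
* **Noise** — NB draws with a single dispersion (default 0.05);
  per-sample library size multipliers scale the means. Gene lengths are
  uniform on [200, 5000] bp and independent of expression, isolating the
  FPKM arithmetic from confounding.
* **Reproducibility** — one integer seed, split into substreams for
  means, counts and lengths; fixed seed gives byte-identical output.

What the generator does **not** emulate: GC/length-dependent coverage
bias, gene–gene correlation, dispersion–mean trends, outlier samples and
batch effects. Passing recovery tests therefore demonstrates the
statistical machinery is correct under the stated model, not that real
tobacco libraries would classify with the same accuracy.

Phenotype simulation draws Gaussian replicates around per-(genotype,
year, stage) means; the built-in `nicotine_trial_means` reconstructs
trait means from the published OPH/BPH table, anchoring the low parent
at 2.0% dry weight and taking the flue-cured female as the high parent.
Ct simulation inverts 2^-ΔΔCt exactly at zero noise.

## Problem sizes

Validation runs use 2000 genes (recovery: 5 replicates/genotype, 4-fold
effects, dispersion 0.05; null control: 3 replicates, dispersion 0.1),
10,000 random triples for the heterosis identity, an 11-gene noiseless
qPCR round trip, and exhaustive small-instance oracles (all
hypergeometric configurations to N = 30; BH vectors to length 6 on a
4-point grid). These sizes give sub-percent Monte-Carlo error on the
reported rates while keeping the full suite near interactive speed.

## Known limitations

* The no-replicate NB test cannot separate biological variability from
  genotype effect; blind pooling makes it conservative, not correct.
* Moment dispersion with a global-median shrinkage target ignores any
  dispersion–mean trend; a trended target would be the natural upgrade.
* The Wald normal reference is mildly anticonservative at n ≤ 3.
* Pattern assignment treats the three tests as independent evidence; no
  joint error control across the three contrasts is attempted beyond BH
  within each contrast.
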