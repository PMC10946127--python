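# Methods

This note records the models behind `landgen`, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical conventions that matter when comparing against other tools.

## The synthetic study design

The generator emulates a gradient × agroecology sampling design: by default
4 geographic gradients, each crossing the three conventional Ethiopian-style
elevation bands — lowland (400–1800 m.a.s.l.), midaltitude (1800–2400) and
highland (2400–3500) — with two village populations per gradient×band cell
plus two extra villages, i.e. 26 populations, and 16 birds per village
(sample sizes of roughly this order are typical of village-poultry surveys;
per-village counts after quality control are rarely published, so a single
round number is used). Each population receives one coordinate and one
elevation drawn uniformly inside its band; environmental predictors are
population-level constants copied to every sample, matching the granularity
of village-level sampling.

Six environmental predictors are generated (elevation, temperature
seasonality, precipitation of the warmest and of the coldest quarter, May
solar radiation, soil clay content). Conditional on the standardized
elevation they follow a configurable target correlation matrix: the
non-elevation block is drawn from the conditional Gaussian implied by that
matrix (Cholesky of the Schur complement), so both predictor–elevation and
predictor–predictor correlations track their targets; a non-positive
semi-definite target is rejected. The default matrix encodes moderate,
plausibly-signed dependence (wetter warm seasons and less May irradiation at
elevation, etc.). Five quantitative traits (body weight, beak length, comb /
wattle / earlobe width) get baseline values with a mild negative elevation
effect and, for comb and wattle width, a shared latent factor
(thermoregulatory appendages co-vary; this also exercises the forced-keep
path of predictor reduction). `simulate_traits` can overwrite these with an
explicit QTL + environment + noise architecture.

## Genotypes: Balding–Nichols over founder mosaics

Ancestral allele frequencies are Uniform(0.05, 0.95). Population frequencies
follow the Balding–Nichols model: Beta(p(1−F)/F, (1−p)(1−F)/F) with F =
`fst_level` (degenerating to the ancestral frequency at F = 0). Each
population receives a founder pool of `founder_haplotypes` (default 100)
haplotypes drawn site-independently at its frequencies; sample haplotypes
are recombinant mosaics of that pool with per-bp switch probability
`recombination_rate` (default 10⁻⁸) and a fresh founder at every chromosome
start. With zero recombination every haplotype is an exact founder copy.

Consequences worth knowing:

* **Haplotype-sharing LD, weak allelic LD.** Identity-by-state between two
  haplotypes decays over a handful of SNPs unless they share a founder, so
  EHH decays on a 10–100 kb scale and hard sweeps (forced identity over a
  span) stand out; but because founders are drawn site-independently,
  allele-frequency covariance between nearby sites is only ~1/K. LD-pruning
  behaviour on real data (long pruned runs) is therefore exercised by
  explicitly planted correlated variants in the tests, not by the generator
  defaults.
* **Founder-pool drift.** The finite pool adds ≈ (1−F)/K among-population
  variance, a small upward bias of the realized differentiation (≈ 0.01 at
  K = 100). Recovery tests of F = 0.10 land around 0.09–0.10, inside the
  ±0.03 acceptance band; true null contrasts are built by splitting one
  population (shared pool), not by simulating two F = 0 demes.
* No coalescent genealogy, mutation model, sex chromosomes or pedigree —
  passing tests say the estimators recover what this generator encodes, not
  that the pipeline is robust to every demographic history.

Injected signals: a hard sweep copies one donor haplotype into a fraction of
the target populations' haplotypes across `[core − span/2, core + span/2]`
(other populations and outside loci bit-identical to the input); an
environmental cline resamples a single locus so per-population frequencies
follow `logistic(logit(baseline) + slope · z(predictor))`. Ground truth is
serialized as JSON beside the VCF so recovery tests never re-derive it.

## Quality control

Filters run in a fixed order — call rate < 0.7, then MAF < 0.05 (strict: a
site at exactly 0.05 is retained), then Hardy–Weinberg exact p < 5×10⁻⁶ —
with removals recorded per filter. The HWE test is the standard exact
conditional test (sum of probabilities of heterozygote configurations no
more probable than observed; not mid-p), computed with log-gamma weights and
verified against exhaustive enumeration to 1e-12. Site-quality (phred)
filtering belongs to variant calling and is only surfaced as an optional
QUAL ≥ threshold pass-through on VCF reading.

LD pruning scans windows of 100 surviving variants advanced by 10; within a
window the lower-MAF member of any pair with r² > 0.5 is removed (tie →
later position), repeating until stable. Windows re-tile over survivors
between passes, so the final set satisfies the audited property: no pair
co-occurring in a window of the final tiling exceeds the threshold. Missing
genotypes are excluded pairwise for r²; a zero-variance vector has r²
defined as 0 (nothing to prune on).

## Selection scans

Per-site FST uses the two-population Weir–Cockerham estimator with the full
heterozygosity correction; sites monomorphic across both populations are
excluded from window means rather than zeroed (zeros would dilute the
signal). Windows are `[1 + k·step, k·step + span]` for
k = 0 … ⌊(L−span)/step⌋+1, last window truncated — a chromosome shorter than
the span yields exactly one truncated window.

EHH around a core is computed outward by incremental refinement of
haplotype groups (an O(n) counting relabel per site), stopping when EHH
drops below 0.05 — the conventional cutoff of haplotype-scan tooling, kept
as an explicit parameter. iHH integrates the curve trapezoidally over bp,
excluding the final sub-cutoff point. Population-level iHH at a site
combines the per-allele iHH of alleles with ≥ 2 carriers, weighted by
carrier count, so near-fixed sites stay defined; cores with pooled MAF
< 0.05 are skipped. XP-EHH = ln(iHH_A/iHH_B) is standardized genome-wide
(not within frequency bins — the simplest convention that preserves exact
antisymmetry under population swap, which is tested). The genome scan runs
in a numba-compiled kernel; a pure-numpy curve implementation is the
reference, and the two are cross-checked in the tests.

Empirical p-values are rank/N with ties taking the worst (largest) rank of
their block; undefined windows are excluded from N. The significance flag
marks p ≤ top_frac (default 0.01): with distinct values exactly
⌊top_frac·N⌋ windows are flagged, and the flagged two-sided windows are
those with |signed −log₁₀p| ≥ 2. Overlap between FST- and XP-EHH-significant
windows is reported with all three candidate denominators (union, either
set) because a single "percent overlap" is ambiguous.

## Ordination

Genotype PCA uses Patterson normalization — mean-impute, center, scale by
√(p(1−p)) — and eigendecomposes the sample covariance M Mᵀ/m; monomorphic
SNPs are dropped with a count.

Partial RDA residualizes the centered (not variance-scaled — the ordination
convention for allele counts, switchable) dosage matrix and the predictors
on [1, Z] with Z = longitude + latitude. Elevation is deliberately a
predictor, not a conditioning variable, since it is part of the
environmental hypothesis. The fitted values of the multivariate least
squares fit are SVD-decomposed; eigenvalue_k = σ_k²/(n−1); the constrained
axis count equals the rank of the residualized predictors (collinear
columns dropped with a warning). R² is the fitted-to-residualized variance
ratio; adjusted R² is Ezekiel's 1−(1−R²)(n−1−q)/(n−1−q−p), undefined when
n ≤ p+q+1. The permutation test permutes rows of the residualized
predictors (999 by default, seeded, add-one p). SNP loadings are
correlations between residualized dosages and site scores; axis signs
follow a deterministic largest-entry-positive convention.

Outliers: per axis among the first three (a fixed knob replacing visual
scree inspection), SNPs beyond 3.5 empirical SDs of the loading mean —
two-tailed normal p = 0.0005, verified to calibrate on a million Gaussian
loadings. The outlier set is the union over axes with each SNP reported
once at its most extreme axis (a per-axis concatenation would double-count
SNPs extreme on two axes). Assignment takes the predictor with maximal |r|
against the residualized dosage (ties by configured order; residualized
rather than raw variables, consistent with the conditioned model); |r| bins
are left-open/right-closed at 0.3/0.4/0.5/0.6.

## Annotation and enrichment

Gene intervals are 1-based inclusive internally; BED input (0-based
half-open) is converted on read, GFF3 taken as-is. A gene maps to a window
on ≥ 1 bp intersection of the full window — not just the top SNP — because
the windowed statistics are themselves window-level quantities. Enrichment
is the upper-tail hypergeometric test over user-supplied gene sets with the
annotation file as default universe, Benjamini–Hochberg q across sets and a
q < 0.1 significance convention.

## Problem sizes used in the test and acceptance runs

Recovery and calibration suites run at desk scale, chosen so each property
is comfortably powered: differentiation recovery on 2×100 diploids ×
20 000 SNPs; sweep recovery on 10 seeds of a 40 Mb / 8 000-SNP genome
(1 600 windows, so the top 1% comfortably covers the ~18 windows inside a
500 kb sweep span) with 2×40 diploids; cline recovery on the full 26-village
design with 1 600 SNPs and 10 seeds; null calibration on 200 small
permutation fits plus one 20 000-SNP zero-heritability association run. The
full suite completes in well under a minute of compute per heavy test.

## Known limitations

* Only two-population FST contrasts (pooled groups form the two sides);
  multi-way estimators are out of scope.
* Physical distance only — no genetic maps; iHH integrates bp.
* The generator's allelic LD is weak between sites (haplotype-sharing LD
  only), so window statistics on simulated data are closer to independent
  per site than on real WGS data.
* Geography conditioning is linear in longitude/latitude; no spatial
  autocorrelation models.
* Enrichment expects user-supplied gene sets; no pathway-database lookups.
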