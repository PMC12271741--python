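# Methods

## Statistical model

The unit of analysis is a protein-coding gene with a branch-specific
evolutionary rate ω = dN/dS, a protein abundance A (ppm), a compartment
class derived from its subcellular location label, and a binary
essentiality call. The working scale is log–log:

    x = log10(A),    y = log10(ω + ε),    ε = 0.01.

The pseudo-count keeps genes whose rate is reported at a shared low-rate
floor (rate-estimation software grants all very low rates the same non-zero
number, which makes the log-ω distribution bimodal) in the analysis without
letting them dominate. ε is a direct parameter; a data-driven rule
ε = 1/min(dS) is provided verbatim for transparency but is internally
puzzling (a typical min dS of ~0.01 would give ε ≈ 100), so the default is
the fixed 0.01.

**Deming regression.** Both x and y are measured with error (protein
quantification and finite-branch rate estimation respectively), so the
primary fit is the errors-in-variables (Deming) estimator with
error-variance ratio δ = Var(err_y)/Var(err_x):

    slope = (s_yy − δ·s_xx + sqrt((s_yy − δ·s_xx)² + 4δ·s_xy²)) / (2·s_xy),
    intercept = ȳ − slope·x̄,

with central sample moments s_xx, s_yy, s_xy. δ defaults to 1 (orthogonal
regression); it is exposed in every API. δ→∞ recovers OLS. When s_xy = 0
the δ-scaled principal axis decides: slope 0 when δ·s_xx ≥ s_yy, an error
(vertical axis) otherwise. Numerically, the closed form loses precision to
cancellation for δ ≳ 10⁸; such extreme ratios are outside any sensible use
here.

**Residuals.** Abundance-controlled rates are vertical residuals
r = y − ŷ(x), including for Deming fits — "controlled rate" is a
y-direction quantity. Signed orthogonal residuals are available as an
option (`fit_residuals(..., orthogonal=True)`).

**LOESS.** The robustness path fits a tricube-weighted local polynomial
(degree 1 by default, degree 2 available), span 0.75 by default, no
robustness iterations. The neighbourhood size is k = ceil(span·n), with
span·n ≥ degree + 2 required. Prediction at new x re-solves the local
weighted fit; when all k neighbours share one x the local mean is used. The
degree-1 smoother agrees with standard lowess implementations away from the
boundary; boundary behaviour may differ slightly between implementations.

**Compartment comparisons.** One-way ANOVAs decompose raw y, x, and r by
compartment; pairwise contrasts use Tukey HSD (studentized range,
Tukey–Kramer harmonic-mean correction for unequal n) or a permutation max-T
adjustment. Degenerate inputs (zero total variance) report F = 0, p = 1.

**Factorial decompositions.** Variance in y (or r) is split over
essentiality, compartment, optional log-abundance covariate, and their
interactions using sequential (Type I) sums of squares computed by
rank-incremental least squares: terms enter one at a time in the caller's
declared order and each SS is the drop in residual SS. Only this partition
makes "percent of variance" sum to exactly 100 with the residual row (an
invariant asserted in tests). The pipeline's printed order is essentiality,
location, their interaction, then abundance and its interactions — the
order the study tables use. Entering abundance first instead shows how much
of the essentiality share is really abundance; that is an option, not the
default. A term whose design columns add no rank is reported as aliased by
name.

**Matched sign test.** Each membrane gene, visited in a seeded random
order, takes the unused cytoplasmic gene closest in log10 abundance
provided the gap is within the window (0.1/0.25/0.5 log10 units swept by
default). Matching is without replacement (with-replacement available
behind a flag). Pairs with exactly equal ω are dropped (standard sign-test
convention). The p-value is the exact one-sided binomial tail at p₀ = 0.5
for "cytoplasmic member faster".

**Permutation null.** Compartment labels are shuffled over all usable
genes, preserving group sizes ("controlling for group size" is read as
size-preserving label shuffles). The statistic — per-class Deming slope
difference, intercept difference, or pooled-fit residual mean difference
(membrane − cytoplasm) — is recomputed per shuffle; the pooled fit itself
is label-invariant and computed once. Two-sided p with the add-one
estimator p = (1 + #{|perm| ≥ |obs|})/(n_perm + 1), never exactly zero;
default n_perm = 10⁴. Permutations with an undefined statistic are redrawn
and counted. The implementation is vectorised (label matrices × moment
vectors) so calibration studies run in seconds; an exact mode enumerates
every distinct label assignment for small n.

**Residual-shape diagnostics.** A nested OLS F-test compares r ~ x against
r ~ x + x² (a concave abundance–rate law leaves an n-shaped residual
pattern); a median split by abundance plus an OLS interaction F-test asks
whether the high- and low-abundance halves share a slope, with per-group
Deming slopes reported descriptively.

## Curation

Dubious orthologs are fenced on per-branch dS: a record is rejected when
any configured dS column exceeds Q3 + k·(Q3 − Q1), k = 1.5, with
linear-interpolation ("type 7") quantiles — stated so fences are
bit-reproducible. Fences are estimated **once** from the input sample and
recorded in the result; curation is idempotent given the recorded fences
(re-estimating fences from an already-curated sample would tighten them and
reject more of the clean upper tail, which is not what a one-shot outlier
filter means). Genes missing a location label or an essentiality call are
rejected when the corresponding requirement is on (both on by default).
Labels containing both "membrane" and "cytoplasm" collapse to Membrane
(membrane anchoring is the physical commitment) and can be flagged as
ambiguous; multi-label inputs must be reduced to one primary label by the
caller.

## Codon-usage abundance proxies

All metrics use the standard genetic code; six-fold families (Leu, Ser,
Arg) are single blocks of degeneracy 6. The first 20 codons are skipped
(AT-enriched 5′ ends are under different selection); the log-odds path uses
a central 10-codon window centred at floor(L/2) and constrained to start no
earlier than codon 21 (reconciling "central" with the skip-20 rule), so
genes shorter than 31 codons are excluded from it.

- **CAI**: geometric mean of relative-adaptiveness weights w over effective
  codons, excluding stops and single-codon families. Weights come either
  from an input table or from a reference corpus via w = count/max within
  each block (floored at 0.01 so the geometric mean stays defined; the
  floor is on the ratio, so weights are invariant to rescaling counts). The
  packaged table `data/cai_weights_synthetic.tsv` is a synthetic example
  for demos and tests, not an empirical organism table.
- **Deviation score**: per degeneracy class d, O = observed optimal-codon
  count among the effective codons in d-fold blocks with a defined optimal
  codon, E = (count of such codons)/d; class score (O−E)/E; final score the
  count-weighted mean over classes (the weighting basis was an open choice;
  effective-codon counts weight classes by the evidence they carry).
- **Log-odds score**: genes ranked by abundance; codon counts over
  central-10 windows tallied for the top and bottom floor(n/4) genes; per
  codon ln of the frequency ratio with Haldane 0.5 pseudo-counts
  (denominators add 0.5·64); a gene's score is the mean over its window.
  "Breadth of codons" is read as the central window.
- **Optimal codons**: per block, the enrichment candidate (highest
  log-odds) must agree with the tRNA candidate (highest supplied tRNA
  weight) — disagreeing blocks are excluded; with no tRNA weights the
  enrichment candidate is used alone and the result is flagged "no-tRNA".

Any of the three gene scores can replace measured abundance in the pooled
regression (the pipeline does this for the log-odds score when a CDS FASTA
is supplied).

## Synthetic data

The generator draws, per gene: a compartment class from configured
proportions; log10 abundance ~ Normal(μ_class, σ_class); log10 ω =
a_class + b_class·log10 A + Normal(0, σ_noise), clamped to a shared floor
(default 10⁻³) with probability floor_prob — the floor is applied after the
regression draw, matching the rate-floor artifact; essentiality ~
Bernoulli(logistic(β₀ + β₁·log10 A)); dS ~ Gamma(shape, scale), ×10 for a
random outlier fraction. True classes, latent means, floor flags and
outlier flags go to a separate truth table, never into the gene table, so
curation tests stay honest.

**Default profiles.** "ecoli-like": 980 genes, class proportions
46.94/42.04/11.02% (Membrane/Cytoplasm/Others), membrane:cytoplasm mean
abundance ratio 1/5; "yeast-like": 4,104 genes, 26.34/27.95/45.71%, ratio
1/15, steeper slopes. With equal within-class log-SDs the ratio of
arithmetic means of the log-normals is exactly 10^(μ_M − μ_C), so the
ratios are encoded directly in the class means.

**Why the defaults invert.** Writing x̄_k, ȳ_k for class means, the
pooled-fit residual contrast is r_M − r_C = (ȳ_M − ȳ_C) − b·(x̄_M − x̄_C)
with pooled slope b. The defaults put the raw contrast ȳ_M − ȳ_C > 0
(membrane faster raw, cytoplasm slowest) while the within-class slopes are
steeper than the between-class-means slope (ȳ_M − ȳ_C)/(x̄_M − x̄_C), which
forces b below that ratio and hence r_M − r_C < 0 (membrane slowest after
control). For the yeast-like profile the margin is large (≈0.1–0.13 in
log10 units against class-mean standard errors of ~0.02), so the inversion
is recovered in effectively every seed; for the ecoli-like profile the
margin is deliberately small — shallow slopes and a 1/5 abundance gap —
so the residual contrast is weak, mirroring a marginally significant
bacterial effect. Within-class log10-abundance SD is 1.0 and rate noise SD
0.35; the free choices (noise, floor probability 0.08–0.10,
essentiality coefficients, gamma dS) are calibration picks for realistic
dispersion, not empirical values.

**What the generator does not emulate:** phylogenetic covariance between
genes, estimation error structure beyond floor+noise, multi-label
locations, context-dependent essentiality, genuine direct essentiality→rate
effects (essentiality links to rate only through abundance, giving a clean
null for decomposition ordering tests; direct effects can be added via
intercept offsets). Passing tests therefore demonstrate that the machinery
recovers the encoded structure, not that real organisms match the
defaults.

Synthetic CDS corpora plant, per synonymous block, one optimal codon used
with probability 1/d + (1 − 1/d)·strength·q at abundance quantile q, genes
of 60 codons by default — enough for both codon windows.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed; the pipeline report is a
pure function of (config, seed) and serialises to byte-identical JSON. The
test suite uses derandomised property tests, 1,000-replicate calibrations
for the permutation and nested-F nulls (n = 60 and 30 per replicate), 100
seeds at the full n = 4,104 for inversion recovery, and 25 seeds in the
acceptance script; these sizes give Monte-Carlo error comfortably below the
asserted margins while keeping runs quick.

## Known limitations

- The Deming fit assumes a single global error-variance ratio δ; no
  gene-specific measurement-error model and no Bayesian errors-in-variables.
- The matched sign test discards unmatchable genes (low-abundance membrane,
  high-abundance cytoplasmic), as any matching design must.
- Tukey HSD assumes approximately equal within-group variances.
- LOESS prediction outside the training range extrapolates the local fit at
  the boundary.
- No multiple-testing correction across the whole report: each test is
  reported as-is, as in the analysis the pipeline reproduces.
- No mixed models or phylogenetic regression; ω, dN, dS are consumed as
  given, never re-estimated from sequences.
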