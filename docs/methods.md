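# Methods

## The calibration problem

Microarray probes report fluorescence intensities that track their target
gene's abundance only up to a probe-specific response: a roughly linear
relationship in log space at non-extreme intensities, bounded below by a
background floor and above by saturation, with per-probe slope and offset
that differ enough that raw intensities cannot be read as absolute
expression.  Some probes are worse than miscalibrated: they hybridize to
the wrong transcript (off-target), or sit at high intensity regardless of
their target's abundance (cross-hybridizing "bright" probes).

Given matched RNA-Seq (gene-level TPM) and microarray (probe-level
intensity) measurements of the same RNA samples, this package

1. scores every probe by the Pearson correlation, across training samples,
   between its log2 intensity and its gene's log2 TPM;
2. converts the one-sided correlation p-values to q-values and passes a
   probe when its correlation is positive with q < 0.1;
3. designates, per gene, the probes with maximal / minimal correlation
   ("best"/"worst") and maximal mean intensity across regions ("highest");
4. fits, for each passing probe, the line that maps the 5th and 95th
   percent quantiles of its log2 intensities onto the same quantiles of
   its gene's log2 TPM —

       m = (q95_seq − q05_seq) / (q95_array − q05_array)
       b = q05_seq − m · q05_array

   so that `SSMI = m · log2(intensity) + b` (a sequencing-scaled microarray
   intensity) lives on absolute log2-TPM scale.

The anchors make two exactness guarantees hold by construction, and both
are asserted in the acceptance suite: applying the fit to its own training
samples reproduces the RNA-Seq anchor quantiles to 1e-9, and on noise-free
data generated as exact inverse-linear probe transforms the fit recovers
the true (m, b) to 1e-9 with every probe at r = 1.

## Normalization

**TbT-style sample scaling (linear space).**  Samples are rescaled by
their total signal over genes *not* differentially expressed between two
groups (neocortex vs non-neocortex in the reference design).  The DE
screen is a per-gene Wilcoxon rank-sum test at Benjamini–Hochberg
FDR < 0.05 — distribution-free and dependency-light; the original
formulation used a Bayesian DE caller, but any reasonable two-group screen
serves the purpose of excluding group-driven genes from the scaling
totals.  Scale factors are normalized to mean 1 (identifiability), and one
global multiplicative constant restores the matrix-wide sum of
log2(value + ε) to its pre-normalization total (conserved to 1e-6; a
`rescale_scope="sample"` option conserves each column's sum instead, since
the conservation statement is ambiguous between the two readings).

**Empirical-Bayes batch adjustment (log2 space).**  The standard
parametric location/scale model: per gene g, Y_ijg = α_g + γ_ig + δ_ig ε_ijg
with batch i.  α̂_g is the batch-size-weighted grand mean and σ̂²_g the mean
squared residual after removing batch means (denominator N); on
standardized data, per-batch location γ̂ and scale δ̂² (within-batch
variance, ddof 1) are shrunk toward a normal / inverse-gamma prior with
method-of-moments hyperparameters (τ² and the δ̂² moments use ddof 1,
matching the widespread R implementation), iterating the two posterior
updates to an absolute tolerance of 1e-4 (max 500 sweeps).  Genes with
zero pooled variance pass through unadjusted and are logged.  When the
scale prior is degenerate (all δ̂² identical, moment variance 0) no
shrinkage is applied — without this guard the inverse-gamma moments are
undefined.

Two consequences of the standard convention mix (pooled variance over N,
within-batch variance over n_i − 1) are worth knowing: the adjustment is
idempotent only up to an O(1/n_i) factor, and a "pure additive shift"
is removed *exactly* only when the location prior is degenerate.  Both are
tested in exactly those regimes; on noisy data the tests assert a ≥ 95%
reduction of the batch gap and a second application changing values far
less than the first.

The implementation is verified at 1e-8 against an independently coded
plain-loop fixed point of the same update equations, and loosely
(atol 0.02) against `scanpy.pp.combat`, which implements the same model
with slightly different conventions (ddof 0 for τ², relative convergence).

**Order of operations.**  The scaling fit consumes data normalized up to
but *not* including the cross-donor batch adjustment, so the held-out
donor remains independent; batch adjustment of SSMIs is available
afterwards for the comparative metrics.

## Probe statistics

The correlation p-value uses t = r·√((n−2)/(1−r²)) with n−2 degrees of
freedom, one-sided for positive correlation by default ("significant
positive correlation" is the pass semantic; two-sided is available but the
positive-r requirement always stands).  It agrees with a 10⁵-draw
permutation oracle within ±0.02 at n = 10.

q-values use the smoother-free λ-grid null-proportion estimate
π̂₀ = mean over λ ∈ {0.05, …, 0.90} of #{p > λ}/(m(1−λ)), clipped to
(0, 1], and q_i = min over p_j ≥ p_i of π̂₀·m·p_j/rank(p_j), capped at 1.
With π̂₀ := 1 this reduces exactly to Benjamini–Hochberg (asserted to
1e-12).

Bright probes are flagged from grand means: least-squares line of mean
log2 intensity on mean log2 TPM over all probes, flag positive residuals
beyond 3 robust standard deviations (1.4826 × MAD).  The robust scale is
essential: probes compressed onto the background floor and the bright
outliers themselves otherwise inflate a plain residual sd and mask the
very outliers being hunted.

## The synthetic-data generator

The generator emulates the reference design at desk scale: 2 donors ×
(22 neocortical + 7 non-neocortical regions) × 2 hemispheres × 2
replicates = 232 samples per platform per run, 2000 genes, ~1.8 probes per
gene, 10⁵ expected fragments per sample.

Gene truth: baseline log2 abundance ~ Normal(1, 3.5), upper-winsorized at
+2.5 sd.  The winsorization keeps the most abundant gene at a few percent
of a sample's TPM; without it a single gene can hold half the library at
this reduced gene count, and the compositional TPM denominator then
transmits that gene's noise to every other gene.  30% of genes carry
regional structure (effect sd 0.4 in neocortex, 0.8 in non-neocortical
regions — transcriptionally more diverse) over a 0.1-sd background common
to all genes; donors contribute per-gene location (sd 0.3) and scale
(log-sd 0.15) effects, which is what makes the batch-adjustment stage
non-trivial.

Sequencing: fragment counts ~ Poisson(depth · relative abundance) with an
extra log-normal sample noise (sd 0.15); TPM = count/total × 10⁶ (columns
sum to 10⁶ exactly).  No gene-length bias is injected; transcript lengths
(log-normal, median 2.5 kb) exist only as a binning key.

Microarray: each on-target probe reports x = (log2 TPM_true − b)/m pushed
through a softplus background floor at log2 = 1 and a hard saturation clip
at 15, plus Gaussian noise (sd 0.3).  Probe slopes are log-normal with
median 1.4 and log-sd 0.4 (quartiles ≈ 1.1–1.8, so half the slopes fall
in 1–2, with realistic tails) and offsets Normal(−1, 3): large offset
spread is deliberate — real probes over- or under-report by orders of
magnitude, and that heterogeneity is precisely what quantile scaling
removes.  10% of probes track a different random gene (off-target), 2%
emit near-saturated constant intensity (bright, 14.5).  Vendor-style
presence flags are fabricated as noise-free signal above the floor.

A zero-noise mode (`SimulationConfig.noise_free()`) switches every noise
source off and disables floor/ceiling; the linear model is then closed and
the pipeline must be exact.  An "other tissue" mode reuses a previous
run's probe layout and transforms while drawing a new expression profile
that shares per-gene baselines up to a Normal(0, 2) shift (cross-tissue
log-expression correlation ≈ 0.8, typical of even very different
tissues), with regional structure redrawn.

**What the generator does not emulate** — hence what passing tests do not
show about real data: isoform structure and length bias, GC and coverage
bias, spatially correlated array artifacts, co-expression between genes
(regional effects are drawn independently per gene, so off-target probes
are uncorrelated with their annotated gene in expectation — real
co-expression would make some off-target probes legitimately
informative), and vendor preprocessing of intensities.

## Regimes, depths and known limitations

Two analyses are coverage-dependent and are run at 10⁶ expected fragments
rather than the generator's default 10⁵: the expression-binned
reproducibility curve (rise then plateau) and the pass-rate vs
training-set-size curve (rise then knee).  At 10⁵ fragments the median
gene receives ~11 counts, the Poisson-limited regime spans the entire
expression range, and both curves are still climbing at the top of the
observable window; at 10⁶ the mid-expression genes are count-saturated,
which is the regime the reference analyses describe.

The cross-tissue transfer property deserves a caution.  Scaling
parameters are a per-probe line anchored at the training tissue's
expression quantiles; the intercept necessarily encodes the training
tissue's per-gene level.  Transferring to a tissue that shares most of
its expression profile (the realistic case) improves absolute-level
agreement for essentially all samples.  Transferring to a hypothetical
tissue with a *fully independent* expression profile inverts the benefit:
weakly measured probes carry noise-dominated slopes, and the anchor
information becomes uninformative.  Equally, probes whose gene is
essentially unexpressed in the training tissue receive meaningless
parameters even though they may pass the correlation screen at large n —
at n = 115 training samples, correlations as weak as r ≈ 0.2 are
significant at q < 0.1.  Filtering at a minimum correlation rather than a
significance level would be the natural extension for transfer-critical
uses.

Off-target error control is honest but approximate: samples within a
region share the regional effect, so the effective sample size of the
null correlation distribution is below the nominal n, and the realized
off-target pass fraction at q < 0.1 sits near 0.10–0.13 (aggregated over
ten runs) rather than at a guaranteed bound.

## Numerical choices

- Quantiles: linear interpolation between order statistics (numpy default,
  the "type 7" convention), recorded in the scaling-table header.
- log2 offset ε defaults to 2⁻¹⁰ for both platforms, configurable; small
  enough not to distort values ≥ 1 TPM.  Zero-count genes map to −10,
  which widens their quantile spans; the noise-free acceptance checks use
  ε = 0 (no zeros exist there).
- Scaling-table floats carry 12 significant digits; read-back reproduces
  them at that precision.
- Constant probes (zero intensity anchor span) are unscalable: excluded
  and logged, never emitted with non-finite parameters.
- Ties in best/worst/highest designation break lexicographically by probe
  id; degenerate ANOVA genes (zero variance everywhere) get p = 1.
- All randomness flows from a single integer seed per run; pipeline
  outputs are byte-identical under a repeated seed, and every output file
  carries the tool version, a config hash and the seed in `#` header
  lines.
- "Carefully selected" training subsamples are region-stratified: first
  one sample per region class, then one per region, then uniform fill.

## Problem sizes

Default test and acceptance runs use 2000 genes (~3600 probes), 232
samples per donor pair, 10⁵–10⁶ fragments per sample, 10 seeded
replications for the error-control aggregate, and 10⁵ permutations /
10⁵ fold-change draws for the oracle and concordance checks.
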