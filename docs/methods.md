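# Methods

## The sliding-window model

For a single tissue, expression is a genes × samples matrix of log2
counts-per-million. Within each age window we fit, per gene, ordinary
least squares on the design

```
[1, Age_c, Sex_c, Age_c·Sex_c]
```

where Age_c is the donor age centered on the window's own mean, Sex_c is
the sex code (female = 0, male = 1) centered the same way, and the
interaction is the elementwise product of the two centered columns. The
intercept is therefore the expression of the window's average sample.
Centering uses within-window means because each window is an independent
model set. In a sex-constant window the Sex and interaction columns are
dropped and those effects reported as missing rather than fitted from a
rank-deficient design.

### Window schedule

Windows are centered on consecutive integer years from ⌈min age⌉ to
⌊max age⌋. The span is 16 years in the interior and tapers linearly to 11
years at the first and last centers:

```
span(c) = min(16, 11 + (c − first), 11 + (last − c))
```

The interval [c − span/2, c + span/2] is closed at both ends, so a donor
sitting exactly on a boundary belongs to both adjacent windows; this
maximizes sample use and keeps the schedule symmetric under age reversal.
Windows with fewer than `min_window_n` members (default 6, enough for a
four-coefficient fit with residual degrees of freedom) are dropped with a
warning. Each window's results are reported at its *representative age*,
the mean donor age of its members — not the center — because skewed
within-window age distributions shift where the evidence actually sits.

### Moderated t-statistics

Gene-wise residual variances s²_g (df = n − p) are shrunk toward a scaled
inverse-χ² prior (d0, s0²) fitted across the genes of the same window by
the closed-form method of moments on log variances: with
e_g = log s²_g − ψ(df/2) + log(df/2), the excess of var(e) over ψ′(df/2)
identifies d0 through the trigamma function (inverted by Newton
iteration), and mean(e) identifies s0². When the excess is non-positive,
d0 = ∞ and every posterior variance equals s0² (with the bias-correction
terms evaluated at the residual df, so that equal input variances are
returned unchanged). The posterior variance is

```
s̃²_g = (d0·s0² + df·s²_g) / (d0 + df)
```

and the moderated t divides each coefficient by s̃_g times its unscaled
standard error, referred to a t distribution with df + d0 degrees of
freedom. This implementation was verified against the reference empirical-
Bayes implementation in R to machine precision (see the test suite).
Hyperparameters are estimated per window, not shared across windows.
Windows with fewer than 10 genes, or with all residual variances zero,
fall back to the ordinary t-test with a warning; genes with exactly zero
residual variance take the prior variance s0² for stability and are
flagged. With d0 forced to 0 the results coincide with ordinary OLS
t-tests, which the tests exercise as an equivalence check.

Per-gene fits are unweighted OLS: the log-CPM transform's precision
weights are not propagated, since the covariate-subtraction step of
pre-processing would invalidate them.

## Pre-processing

Applied per tissue, in order:

1. tissues with fewer than 50 samples are discarded (strict <);
2. genes are kept when their CPM (on raw library sizes) is ≥ 1 in ≥ 40%
   of samples, both comparisons inclusive — the filter is idempotent;
3. TMM normalization factors: the reference sample is the one whose
   upper-quartile CPM is closest to the mean upper-quartile; gene-wise
   log-ratios (M) against the reference are trimmed 30% from each tail of
   M and 5% from each tail of average abundance (A), averaged with
   inverse-asymptotic-variance weights, and the factors rescaled to unit
   geometric mean. Genes with a zero count in either member of a pair are
   excluded. The implementation reproduces the standard R implementation
   to 6 decimal places on test fixtures;
4. log2-CPM: `log2((count + 0.5) / (lib_size·factor + 1) × 1e6)`;
5. covariate screen: PCA on the gene-centered (not scaled) matrix;
   each covariate is tested against PCs 1–2 by Spearman correlation
   (numeric, ≥ 15 unique values), two-sample t (binary), or one-way ANOVA
   (more than two levels, or numeric with < 15 unique values); flagged
   when p < 0.05 and |ρ| > 0.3, |t| > 10, or F > 20 respectively. The
   ANOVA threshold is read as a threshold on the F statistic — the only
   sensible interpretation. The number of detected genes per sample
   (count > 0) is available as the `n_detected` covariate;
6. missing covariates are imputed deterministically — median for numeric,
   mode for categorical, imputed cells flagged — rather than by stochastic
   chained equations, trading a little fidelity for exact reproducibility
   of the whole pre-processing stage;
7. flagged covariates are removed jointly in one OLS design per gene
   (intercept + all covariates, categoricals dummy-coded); the fitted
   covariate contributions are subtracted and a single global offset
   restores the pre-correction matrix minimum, keeping values on an
   interpretable log-CPM scale.

## Alteration profiles and permutation FDR

Per window and effect, the profile is the percentage of genes with
moderated-t p ≤ 0.01 (inclusive), over genes with a non-missing p in that
window. Significance of each percentage comes from a window-specific
permutation null: the (age, sex) pairs of the window's samples are
shuffled *jointly* (one permutation of sample labels) against their
expression columns — preserving the age–sex joint distribution — the
window refitted and moderated, and the percentage recomputed. The
reported quantity is the +1-smoothed empirical tail probability

```
fdr = (1 + #{permuted % ≥ observed %}) / (1 + n_perm)
```

which can never be 0 and is at least 1/(n_perm+1). It is kept under the
name "FDR" in outputs for continuity with the field's usage, but it is a
per-window empirical tail probability, not a Benjamini–Hochberg rate.
The null is window-specific rather than pooled because window sizes (and
hence the sampling variability of the percentage) differ. An independent
permutation of age and sex separately is available behind a flag. The
default permutation count is 50,000; tests and the acceptance script use
500–2,000, which bounds the resolvable FDR at 1/501–1/2001 and is
sufficient for the calibration and recovery checks performed.

*Peaks* are maximal runs of consecutive windows with FDR at or below a
cutoff (default 0.05); the apex of a run is its window of largest
percentage (ties resolve to the youngest representative age) and its gene
table is ordered by ascending p. A user-supplied gene set can be profiled
over age by a per-window 2×2 Fisher test of set membership against
alteration, with the window's tested genes as background; the odds ratio
is the conditional maximum-likelihood estimate.

## GSEA over age windows

Genes are ranked by moderated t, most positive first, ties broken by gene
id so rankings are deterministic. The enrichment score is the extremum of
the weighted Kolmogorov–Smirnov running sum (hit increments ∝ |t|^w with
w = 1; w = 0 gives the classic KS statistic and is available for
testing). The null is built from size-matched random gene sets drawn from
the ranked universe — on a preranked input a sample-permutation null is
not available — with NES = ES / mean(|null ES| of the same sign) and a
+1-smoothed one-sided tail p among same-sign nulls. Sets are restricted
to 15–500 genes after intersection with the universe. BH adjustment runs
across sets within each window; no cross-window correction is applied,
mirroring per-window reporting. The reporting filter keeps sets with
adjusted p ≤ 0.05 in at least one window belonging to a significant peak,
then narrows to the top 1% of sets per effect, i.e. ⌈0.01 × n_sets⌉ sets
ranked by their best peak-window adjusted p. The leading edge is the hits
up to the extremum for positive ES and from the extremum onward for
negative ES.

## Pathway families

Similarity of two gene sets is the overlap index
OI(i,j) = |Gi∩Gj| / min(|Gi|,|Gj|): 1 for identical or nested sets, 0 for
disjoint ones. Pathways fully contained in another pathway are removed
first (identical sets keep the lexicographically first name). Rows of the
OI matrix are correlated pairwise (Pearson, diagonal included; a
zero-variance row gets correlation 0 with a warning), Euclidean distances
are computed between rows of the correlation matrix — the literal
composition of the two steps; the alternative 1 − r distance is available
behind the clustering call — and complete-linkage clustering is cut to
exactly K = 10 families by default. Removed subset pathways inherit the
family of their smallest parent (ties lexicographic), which maximizes
daughter–parent similarity. Family content is summarized by token
frequencies of member names (lowercased, split on non-alphanumerics,
small stop-word list including "pathway", "signaling", "regulation"),
replacing word-cloud rendering with a table. The module is fully
deterministic and invariant to input order up to family relabelling.

## Co-expression modules

Genes passing an across-sample variance threshold enter the network.
Pairwise similarity is the biweight midcorrelation: deviations from the
median weighted by (1 − u²)² for |u| < 1 with u = deviation / (9·MAD); a
gene with zero MAD falls back to plain Pearson for all its pairs, with a
warning. The network is unsigned — a_ij = |cor|^β with β = 12 by default,
checked by the scale-free fit table (connectivity binned into 10
equal-width bins, R² of log-frequency on log-connectivity; a scale-free
network shows high R² with negative slope; equal-count binning would make
the frequency constant by construction, so equal-width bins are used).
The topological overlap is

```
TOM_ij = (Σ_u a_iu·a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),  TOM_ii = 1
```

and modules are branches of the average-linkage dendrogram of 1 − TOM cut
at a fixed height, kept at ≥ `min_module_size` genes and labelled by
decreasing size; everything else is "unassigned". Average linkage and the
unsigned network are the conventional defaults of this framework and both
are configurable. Four shipped per-tissue configurations (variance
threshold, minimum module size, cut height, power) are
(0.5, 15, 0.95, 12), (0.4, 20, 0.98, 12), (0.35, 20, 0.99, 12) and
(0.9, 15, 0.97, 12).

The module eigengene is the first right singular vector of the module's
gene-standardized submatrix, unit norm, sign-oriented to correlate
positively with the module's mean standardized profile (so a global sign
flip of the inputs mirrors the reported trend); variance explained is
σ₁²/Σσ². Enrichment against cell-type or disease signatures is a 2×2
Fisher test per (module, signature) with the network's input genes as
background, conditional-MLE odds ratio, BH adjustment across signatures
within a module, and significance flagged at OR > 1 and p < 0.05.
Disease association is supported only through generic gene–disease
tables fed to the same Fisher path.

## Synthetic cohorts

The generator emulates a single-tissue bulk cohort: donor ages uniform on
20–70 or an older-heavy mixture (30% uniform over the range, 70% over its
upper half) mimicking post-mortem collections; two sexes; baseline
per-gene log2-CPM drawn N(4, 1.5²); library sizes log-normal (σ = 0.3)
around 10⁶; counts negative-binomial with dispersion 0.1 (gamma–Poisson).
Age effects are sigmoidal in age, centered at the onset τ (default 50)
with a 4-year scale, so a window-local slope exists and windows far from
τ show attenuated effects — step effects would concentrate all evidence
in one boundary window. Sex effects are mean shifts; interaction genes
age in one sex only; covariate genes track a binary cohort indicator.
Amplitudes default to 1 log2-CPM with random sign. The truth table
records class, onset, amplitude and direction per gene.

What the generator does *not* emulate: shared donors across tissues,
correlated gene–gene baseline structure beyond the injected classes,
GC/length biases, or batch structure richer than one binary covariate.
Passing tests therefore demonstrate correctness of the machinery and its
calibration under a realistic noise model, not performance on any real
tissue collection.

## Numerical and interface choices

* All stage outputs are TSV with one header row, floats at 10 significant
  digits; identical config + seed gives byte-identical outputs.
* Tie-breaks are deterministic everywhere (lexicographic gene/pathway
  ids, youngest representative age for peak apexes).
* The empirical-Bayes prior fit inverts the trigamma function by Newton
  iteration to relative tolerance 1e-8; the test oracle inverts it
  independently by bisection.
* Fisher p-values use the exact two-sided test; odds ratios are
  conditional-MLE, so a zero margin reports 0 or ∞ rather than an
  arbitrary continuity correction.
* Degenerate inputs are flagged, never silently dropped: unusable windows
  appear in the window-info table with a reason, constant covariates and
  zero-variance genes produce warnings.

## Problem sizes used in the checks

The shipped tests and the acceptance script run at desk scale: cohorts of
120–200 samples and 300–2,000 genes, 100–2,000 permutations, 100–500
random-set null draws, 40-pathway collections and 80-gene networks.
These sizes keep every calibration check (the 0.01 rule within 3
Monte-Carlo standard errors, FDR spread, peak-apex recovery within ±3
years of the injected onset) statistically meaningful while the full
suite completes in a few minutes.

## Known limitations

* The "FDR" of the profiles is an empirical tail probability; it does not
  control a false-discovery *rate* across windows.
* Windows overlap heavily, so neighbouring profile values are strongly
  correlated; runs of significant windows must be read as one event, which
  is exactly what the peak construct does.
* No spline/nonlinear age models, donor-level random effects, surrogate
  variable estimation, or cross-tissue joint normalization.
* The moderation fallback below 10 genes makes very small panels behave
  like plain OLS.
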