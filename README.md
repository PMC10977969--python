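# sharplm

Sliding-age-window linear modelling of bulk tissue transcriptomes across
adult ageing.

Bulk RNA-seq cohorts such as post-mortem tissue banks sample donors across
the whole adult age range, but transcriptomic change with age is neither
linear nor synchronous: different tissues remodel at different ages, and
many genes shift only within a narrow age period. `sharplm` profiles this
by fitting, for every gene, a linear model inside a window of donor ages
that slides through consecutive years:

```
GE ~ E0 + α·Age + β·Sex + χ·(Age×Sex) + ε
```

with Age and Sex centered within the window and the interaction their
product. Windows span 16 years in the interior of the age range and taper
to 11 years at the edges so that the youngest and oldest donors still
contribute to several models. Gene-wise residual variances are shrunk by
empirical Bayes (a scaled inverse-χ² prior fitted across genes by the
closed-form method of moments on log variances), yielding moderated
t-statistics and p-values per gene, window, and effect.

On top of the windowed fits the package provides:

* **Alteration profiles** — per window and effect, the percentage of genes
  with p ≤ 0.01, with an empirical FDR obtained by jointly permuting the
  samples' (age, sex) pairs within each window and refitting; maximal runs
  of significant windows form *peaks*, the age periods of strongest change.
* **GSEA over age windows** — preranked enrichment on the moderated-t
  ranking (weighted Kolmogorov–Smirnov ES, size-matched random-set null,
  NES, BH adjustment) with the pipeline's reporting filters.
* **Pathway families** — gene sets from several databases clustered by
  their overlap index OI(i,j) = |Gi∩Gj| / min(|Gi|,|Gj|) into ten families,
  with subset pathways inheriting the family of their smallest parent.
* **Co-expression modules** — biweight midcorrelation, soft thresholding,
  topological overlap, static tree cut, module eigengenes (first right
  singular vector of the standardized module submatrix) and Fisher
  enrichment against cell-type/disease signatures.
* **Synthetic cohorts** — a seeded generator of realistic age-stratified
  cohorts (negative-binomial counts, log-normal library sizes, sigmoidal
  age effects with a configurable onset) with full ground truth, so every
  stage is testable without downloading any dataset.

## Worked example

```python
import sharplm as sl

# cohort of 200 donors aged 20-70; 10% of 2,000 genes shift with age
# around an onset of 50 years (1 log2-CPM amplitude)
spec = sl.CohortSpec(n_samples=200, n_genes=2000, frac_age=0.10,
                     onset_age=50.0, amplitude=1.0, seed=1)
counts, samples, truth = sl.generate_cohort(spec)

factors = sl.tmm_factors(counts)           # TMM normalization factors
expr = sl.log_cpm(counts, factors)         # log2 counts-per-million
schedule = sl.build_window_schedule(samples)
profile = sl.permutation_fdr(expr, samples, schedule, n_perm=500, seed=1)
peaks = sl.find_peaks(profile, fdr_thresh=0.05)

apex = max(peaks.peaks["Age"], key=lambda p: p.apex_percent)
print(f"windows: {len(schedule)} (spans "
      f"{schedule.windows[0].span:.0f}-{max(w.span for w in schedule):.0f} years)")
print(f"dominant Age peak: {apex.start_age:.1f}-{apex.end_age:.1f} years, "
      f"apex at {apex.apex_age:.1f} years with "
      f"{apex.apex_percent:.1f}% of genes altered (FDR <= 0.05)")
```

prints

```
windows: 49 (spans 11-16 years)
dominant Age peak: 36.7-58.4 years, apex at 49.9 years with 10.3% of genes altered (FDR <= 0.05)
```

i.e. the sliding-window models localize the injected transcriptomic
shift: the peak of altered genes spans the onset, its apex sits within a
year of the true onset age (50), and the apex percentage matches the
injected 10% of affected genes.

The same pipeline is available from the shell:

```bash
sharplm simulate   --out sim --seed 1 --n-samples 200 --n-genes 2000 --frac-age 0.1
sharplm preprocess --counts sim/counts.tsv --samples sim/samples.tsv --out pre --min-samples 10
sharplm sharplm    --expr pre/logcpm.tsv --samples pre/samples.tsv --out lm
sharplm profile    --expr pre/logcpm.tsv --samples pre/samples.tsv --out prof --n-perm 500 --seed 1
sharplm gsea       --results lm/results.tsv --gmt sets.gmt --out enr --peaks prof/peaks.json
sharplm families   --gmt reactome.gmt --gmt kegg.gmt --out fam
sharplm modules    --expr pre/logcpm.tsv --samples pre/samples.tsv --out mods
```

Every subcommand writes TSV/JSON outputs plus a `manifest.json` recording
the configuration, seed, and package versions; identical config and seed
give byte-identical outputs.

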