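"""Per-tissue pre-processing: filtering, TMM normalization, log-CPM,
covariate screening and covariate-effect removal.

The stages mirror the conventional bulk RNA-seq workflow: tissues with too
few samples are discarded, lowly expressed genes removed, library sizes
rescaled by trimmed-mean-of-M-values (TMM) factors, counts transformed to
log2 counts-per-million, technical covariates screened against the first
two principal components of expression, and the flagged covariates'
fitted contributions subtracted gene-wise.  The corrected matrix is
offset so its minimum equals the pre-correction minimum, keeping values
on an interpretable log-CPM scale.  Everything here is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CountMatrix, LogExpressionMatrix, SampleTable

logger = logging.getLogger("sharplm")

__all__ = [
    "filter_tissues",
    "filter_genes",
    "tmm_factors",
    "log_cpm",
    "detected_genes",
    "screen_covariates",
    "impute_covariates",
    "remove_covariate_effects",
    "CovariateScreenReport",
]


def filter_tissues(samples: SampleTable, min_samples: int = 50) -> SampleTable:
    """Drop tissues with fewer than ``min_samples`` samples (strict <)."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    counts = samples.table["tissue"].value_counts()
    keep = counts.index[counts >= min_samples]
    dropped = sorted(set(counts.index) - set(keep))
    if dropped:
        logger.info("filter_tissues: dropped %s (< %d samples)", dropped, min_samples)
    if len(keep) == 0:
        raise ValueError("no tissue passes filter")
    sub = samples.table[samples.table["tissue"].isin(keep)]
    return SampleTable(sub, samples.age_range)


def filter_genes(
    counts: CountMatrix, min_cpm: float = 1.0, min_fraction: float = 0.40
) -> CountMatrix:
    """Keep genes with CPM >= ``min_cpm`` in at least ``min_fraction`` of samples.

    Both comparisons are inclusive; CPM is computed on raw library sizes.
    """
    cpm = counts.cpm().to_numpy()
    frac = (cpm >= min_cpm).mean(axis=1)
    keep = frac >= min_fraction
    if not keep.any():
        raise ValueError("no gene passes the expression filter")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filter_genes: dropped %d of %d genes", n_dropped, len(keep))
    return CountMatrix(counts.counts.loc[keep])


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2**)."""
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        return 1.0
    o, r = obs[ok].astype(float), ref[ok].astype(float)
    po, pr = o / n_obs, r / n_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # asymptotic (delta-method) binomial variance of M
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    # edgeR degenerate guard: nothing to trim or M essentially constant
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = int(np.floor(n * trim_m)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_a)) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(
    counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factor per sample.

    The reference sample is the one whose upper-quartile CPM is closest to
    the mean upper-quartile.  Gene-wise log-ratios (M) against the
    reference are doubly trimmed — ``trim_m`` from each tail of M and
    ``trim_a`` from each tail of average log abundance (A) — and averaged
    with inverse-asymptotic-variance weights.  Genes with a zero count in
    either member of a pair are excluded.  Factors are rescaled so their
    geometric mean is 1.
    """
    lib = counts.lib_size.to_numpy(dtype=float)
    if (lib == 0).any():
        zero = counts.sample_ids[lib == 0].tolist()
        raise ValueError(f"samples with zero library size: {zero}")
    mat = counts.counts.to_numpy(dtype=float)
    uq = np.array(
        [np.quantile(mat[:, j][mat[:, j] > 0] / lib[j], 0.75) if (mat[:, j] > 0).any()
         else 0.0 for j in range(mat.shape[1])]
    )
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = mat[:, ref_idx]
    n_ref = lib[ref_idx]
    factors = np.array(
        [
            _tmm_pair(mat[:, j], ref, lib[j], n_ref, trim_m, trim_a)
            for j in range(mat.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="tmm_factor")


def log_cpm(counts: CountMatrix, factors: pd.Series | None = None) -> LogExpressionMatrix:
    """log2 counts-per-million with the standard half-count offset.

    value(g, s) = log2((count + 0.5) / (lib_size * factor + 1) * 1e6).
    """
    lib = counts.lib_size.to_numpy(dtype=float)
    if factors is None:
        f = np.ones(len(lib))
    else:
        f = factors.reindex(counts.sample_ids).to_numpy(dtype=float)
    eff = lib * f + 1.0
    vals = np.log2((counts.counts.to_numpy(dtype=float) + 0.5) / eff * 1e6)
    df = pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids)
    return LogExpressionMatrix(df, provenance=("log_cpm",))


def detected_genes(counts: CountMatrix) -> pd.Series:
    """Number of genes with count > 0 per sample (the ``n_detected`` covariate)."""
    return (counts.counts > 0).sum(axis=0).rename("n_detected")


@dataclass
class CovariateScreenReport:
    """Per (covariate, PC) association tests against expression PCs 1-2.

    ``table`` columns: covariate, pc, test, statistic, p_value, flagged.
    A covariate is flagged when on PC1 or PC2 its p < 0.05 and its
    statistic exceeds the empirical threshold (|rho| > 0.3 for Spearman,
    |t| > 10 for two-group t, F > 20 for ANOVA).
    """

    table: pd.DataFrame

    @property
    def flagged(self) -> list[str]:
        t = self.table
        return sorted(t.loc[t["flagged"], "covariate"].unique())


_SCREEN_THRESHOLDS = {"spearman": 0.3, "t": 10.0, "anova": 20.0}


def _screen_one(values: pd.Series, pc_scores: np.ndarray) -> tuple[str, float, float]:
    """Route one covariate to Spearman / t / ANOVA against one PC."""
    numeric = pd.api.types.is_numeric_dtype(values)
    n_unique = values.nunique()
    if numeric and n_unique >= 15:
        rho, p = stats.spearmanr(values.to_numpy(dtype=float), pc_scores)
        return "spearman", float(rho), float(p)
    levels = values.astype(str) if not numeric else values
    groups = [pc_scores[(levels == lv).to_numpy()] for lv in levels.unique()]
    if len(groups) == 2:
        t, p = stats.ttest_ind(groups[0], groups[1], equal_var=True)
        return "t", float(t), float(p)
    f, p = stats.f_oneway(*groups)
    return "anova", float(f), float(p)


def screen_covariates(
    expr: LogExpressionMatrix,
    samples: SampleTable,
    covariates: list[str] | None = None,
    p_threshold: float = 0.05,
    thresholds: dict[str, float] | None = None,
) -> CovariateScreenReport:
    """Flag covariates associated with the first two expression PCs.

    PCA is computed on gene-centered (not scaled) expression.  Numeric
    covariates with >= 15 unique values are tested by Spearman
    correlation, binary categoricals by two-sample t-test, and
    categoricals with more than two levels (or numerics with fewer than
    15 unique values) by one-way ANOVA.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for PCA screening")
    thr = dict(_SCREEN_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    if covariates is None:
        covariates = samples.covariate_names
    meta = samples.table.loc[expr.sample_ids]

    mat = expr.values.to_numpy(dtype=float)
    centered = (mat - mat.mean(axis=1, keepdims=True)).T  # samples x genes
    # PC scores via SVD of the sample-space matrix
    u, s, _ = np.linalg.svd(centered - centered.mean(axis=0), full_matrices=False)
    scores = u[:, :2] * s[:2]

    rows = []
    for cov in covariates:
        values = meta[cov]
        obs = values.dropna()
        if obs.nunique() <= 1:
            logger.warning("screen_covariates: %r constant, skipped", cov)
            continue
        mask = values.notna().to_numpy()
        for pc in (1, 2):
            test, stat, p = _screen_one(values[mask], scores[mask, pc - 1])
            limit = thr[test]
            stat_ok = abs(stat) > limit if test in ("spearman", "t") else stat > limit
            rows.append(
                {
                    "covariate": cov,
                    "pc": pc,
                    "test": test,
                    "statistic": stat,
                    "p_value": p,
                    "flagged": bool(p < p_threshold and stat_ok),
                }
            )
    return CovariateScreenReport(pd.DataFrame(rows))


def impute_covariates(
    samples: SampleTable, covariates: list[str] | None = None
) -> SampleTable:
    """Fill missing covariate values: median (numeric) or mode (categorical).

    Imputed cells are recorded in a ``<name>_imputed`` provenance column.
    Fails if a covariate is entirely missing or more than half missing.
    """
    df = samples.table.copy()
    if covariates is None:
        covariates = samples.covariate_names
    for cov in covariates:
        col = df[cov]
        n_missing = int(col.isna().sum())
        if n_missing == 0:
            continue
        if n_missing == len(col):
            raise ValueError(f"covariate {cov!r} entirely missing")
        if n_missing / len(col) >= 0.5:
            raise ValueError(f"covariate {cov!r} missing in >= 50% of samples")
        if pd.api.types.is_numeric_dtype(col):
            fill = col.median()
        else:
            fill = col.mode(dropna=True).sort_values().iloc[0]
        flag = col.isna()
        df[cov] = col.fillna(fill)
        df[f"{cov}_imputed"] = flag.astype(int)
    return SampleTable(df, samples.age_range)


def _covariate_design(meta: pd.DataFrame, covariates: list[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + numeric columns + dummy-coded categoricals."""
    cols = [np.ones(len(meta))]
    names = ["intercept"]
    for cov in covariates:
        col = meta[cov]
        if col.isna().any():
            raise ValueError(f"covariate {cov!r} has missing values; impute first")
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(cov)
        else:
            dummies = pd.get_dummies(col.astype(str), drop_first=True)
            for level in dummies.columns:
                cols.append(dummies[level].to_numpy(dtype=float))
                names.append(f"{cov}[{level}]")
    return np.column_stack(cols), names


def remove_covariate_effects(
    expr: LogExpressionMatrix, samples: SampleTable, covariates: list[str]
) -> LogExpressionMatrix:
    """Subtract fitted covariate contributions from every gene, then offset.

    Per gene an ordinary least-squares fit on [intercept + covariates];
    the fitted contributions of the covariates (not the intercept) are
    subtracted jointly for all requested covariates, and a single global
    additive offset restores the pre-correction matrix minimum.
    """
    if not covariates:
        return expr
    meta = samples.table.loc[expr.sample_ids]
    x, names = _covariate_design(meta, covariates)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(f"rank-deficient covariate design (columns {names})")
    y = expr.values.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    contribution = x[:, 1:] @ beta[1:, :]  # exclude intercept
    corrected = (y - contribution).T
    floor = expr.floor if expr.floor is not None else float(expr.values.to_numpy().min())
    corrected += floor - corrected.min()
    df = pd.DataFrame(corrected, index=expr.gene_ids, columns=expr.sample_ids)
    return LogExpressionMatrix(
        df, provenance=expr.provenance + ("covariates_removed",), floor=floor
    )
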