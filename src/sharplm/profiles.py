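"""Percent-altered-genes profiles across age windows, permutation-based
empirical FDR, peak detection, and user-gene-set Fisher profiles.

For each window and effect, the profile records the percentage of genes
whose moderated-t p-value falls at or below a threshold (default 0.01).
Significance of each percentage is assessed against a window-specific
null built by jointly shuffling the samples' (age, sex) pairs against
their expression columns and refitting the window model; the reported
quantity is the +1-smoothed empirical tail probability

    fdr = (1 + #{permuted percent >= observed percent}) / (1 + n_perm)

kept under the name "FDR" in outputs for continuity with the field's
usage, although it is an empirical tail probability rather than a
Benjamini-Hochberg style rate.  Maximal runs of consecutive windows
below an FDR cutoff form peaks — the age periods of strongest
transcriptomic change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .datatypes import LogExpressionMatrix, SampleTable
from .windows import (
    EFFECTS,
    WindowSchedule,
    WindowedEffectResults,
    build_design,
    build_window_schedule,
    fit_window_model,
    moderate,
)

logger = logging.getLogger("sharplm")

__all__ = [
    "AlterationProfile",
    "Peak",
    "PeakSet",
    "percent_altered",
    "permutation_fdr",
    "find_peaks",
    "geneset_fisher_profile",
]


@dataclass
class AlterationProfile:
    """Per (window, effect): percent altered, counts and empirical FDR.

    ``table`` columns: center_year, representative_age, effect,
    percent_altered, n_genes, n_altered, empirical_fdr (NaN until a
    permutation null has been run).
    """

    table: pd.DataFrame
    p_thresh: float = 0.01
    n_perm: int | None = None

    def for_effect(self, effect: str) -> pd.DataFrame:
        sub = self.table[self.table["effect"] == effect]
        return sub.sort_values("center_year").reset_index(drop=True)


def percent_altered(
    results: WindowedEffectResults, p_thresh: float = 0.01
) -> AlterationProfile:
    """Percentage of genes with p <= ``p_thresh`` per window and effect.

    Only genes with a non-missing p-value in a window count toward its
    denominator; a window with zero testable genes for an effect gets a
    missing entry with a warning.
    """
    rows = []
    for (center, effect), sub in results.table.groupby(
        ["center_year", "effect"], sort=True
    ):
        tested = sub["p"].notna()
        n_genes = int(tested.sum())
        rep_age = float(sub["representative_age"].iloc[0])
        if n_genes == 0:
            logger.warning(
                "percent_altered: window %s effect %s has no testable genes",
                center, effect,
            )
            rows.append(
                {
                    "center_year": center,
                    "representative_age": rep_age,
                    "effect": effect,
                    "percent_altered": np.nan,
                    "n_genes": 0,
                    "n_altered": 0,
                    "empirical_fdr": np.nan,
                }
            )
            continue
        n_altered = int((sub.loc[tested, "p"] <= p_thresh).sum())
        rows.append(
            {
                "center_year": center,
                "representative_age": rep_age,
                "effect": effect,
                "percent_altered": 100.0 * n_altered / n_genes,
                "n_genes": n_genes,
                "n_altered": n_altered,
                "empirical_fdr": np.nan,
            }
        )
    return AlterationProfile(pd.DataFrame(rows), p_thresh=p_thresh)


def _percent_from_window(y, x_perm, design, ysq, xtx_inv, stdev_unscaled, df, p_thresh):
    """Percent altered per effect for one (possibly permuted) window design.

    Row permutation of the design leaves X'X unchanged, so the Gram
    inverse and unscaled SEs are precomputed once per window.
    """
    from .windows import WindowFit  # local import keeps the hot path lean

    xy = y @ x_perm  # genes x p
    coef = xy @ xtx_inv.T
    rss = ysq - np.einsum("ij,ij->i", coef, xy)  # RSS = y'y - b'X'y
    sigma2 = np.maximum(rss, 0.0) / df
    fit = WindowFit(coef, sigma2, stdev_unscaled, df, design, None)
    mod = moderate(fit)
    out = {}
    for effect in EFFECTS:
        if effect in design.effect_cols:
            j = design.effect_cols[effect]
            out[effect] = float(np.mean(mod.p[:, j] <= p_thresh)) * 100.0
        else:
            out[effect] = np.nan
    return out


def permutation_fdr(
    expr: LogExpressionMatrix,
    samples: SampleTable,
    schedule: WindowSchedule | None = None,
    n_perm: int = 50_000,
    seed: int = 1,
    p_thresh: float = 0.01,
    joint: bool = True,
) -> AlterationProfile:
    """Empirical FDR of per-window percent-altered by covariate permutation.

    Within each window the (age, sex) pairs are shuffled jointly against
    the expression columns ``n_perm`` times, the window model refitted
    and the percent altered recomputed; the FDR of the observed percent
    is its +1-smoothed upper tail probability in that window-specific
    null.  ``joint=False`` permutes ages and sexes independently instead
    (breaking their joint distribution).  Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if schedule is None:
        schedule = build_window_schedule(samples)
    rng = np.random.default_rng(seed)
    meta = samples.table
    rows = []
    for window in schedule:
        ids = list(window.sample_ids)
        ages = meta.loc[ids, "age"].to_numpy()
        sexes = meta.loc[ids, "sex"].to_numpy()
        try:
            design = build_design(ages, sexes)
        except ValueError as exc:
            logger.warning("permutation_fdr: window %d unusable: %s", window.center, exc)
            continue
        y = expr.values[ids].to_numpy(dtype=float)
        x = design.matrix
        df = x.shape[0] - x.shape[1]
        xtx_inv = np.linalg.inv(x.T @ x)
        stdev_unscaled = np.sqrt(np.diag(xtx_inv))
        ysq = np.einsum("ij,ij->i", y, y)
        observed = _percent_from_window(
            y, x, design, ysq, xtx_inv, stdev_unscaled, df, p_thresh
        )
        n_genes = y.shape[0]
        exceed = {e: 0 for e in EFFECTS}
        n = x.shape[0]
        for _ in range(n_perm):
            if joint:
                # row permutation leaves X'X unchanged
                perm = rng.permutation(n)
                permuted = _percent_from_window(
                    y, x[perm], design, ysq, xtx_inv, stdev_unscaled, df, p_thresh
                )
            else:
                d_perm = build_design(
                    ages[rng.permutation(n)], sexes[rng.permutation(n)]
                )
                xp = d_perm.matrix
                xtx_inv_p = np.linalg.inv(xp.T @ xp)
                permuted = _percent_from_window(
                    y, xp, d_perm, ysq, xtx_inv_p,
                    np.sqrt(np.diag(xtx_inv_p)), df, p_thresh,
                )
            for e in EFFECTS:
                if not np.isnan(observed[e]) and permuted[e] >= observed[e]:
                    exceed[e] += 1
        for effect in EFFECTS:
            pct = observed[effect]
            fdr = (
                (1.0 + exceed[effect]) / (1.0 + n_perm)
                if not np.isnan(pct)
                else np.nan
            )
            rows.append(
                {
                    "center_year": window.center,
                    "representative_age": window.representative_age,
                    "effect": effect,
                    "percent_altered": pct,
                    "n_genes": n_genes if not np.isnan(pct) else 0,
                    "n_altered": int(round(pct / 100.0 * n_genes)) if not np.isnan(pct) else 0,
                    "empirical_fdr": fdr,
                }
            )
    return AlterationProfile(pd.DataFrame(rows), p_thresh=p_thresh, n_perm=n_perm)


@dataclass(frozen=True)
class Peak:
    """One maximal run of consecutive significant windows."""

    effect: str
    start_center: int
    end_center: int
    start_age: float       # representative age of the first window
    end_age: float         # representative age of the last window
    apex_center: int
    apex_age: float
    apex_percent: float
    centers: tuple[int, ...] = ()


@dataclass
class PeakSet:
    """Per effect: disjoint, age-ordered peaks with apex gene rankings."""

    peaks: dict[str, list[Peak]] = field(default_factory=dict)
    apex_genes: dict[tuple[str, int], pd.DataFrame] = field(default_factory=dict)
    fdr_thresh: float = 0.05

    def __len__(self) -> int:
        return sum(len(v) for v in self.peaks.values())

    def all_peaks(self) -> list[Peak]:
        return [p for peaks in self.peaks.values() for p in peaks]

    def peak_centers(self, effect: str) -> set[int]:
        return {c for p in self.peaks.get(effect, []) for c in p.centers}


def find_peaks(
    profile: AlterationProfile,
    fdr_thresh: float = 0.05,
    results: WindowedEffectResults | None = None,
) -> PeakSet:
    """Maximal runs of consecutive windows with empirical FDR <= threshold.

    The apex of each run is its window of largest percent altered (ties
    resolved toward the youngest representative age).  When the windowed
    results are supplied, each apex gets a gene table ordered by
    ascending p-value for that effect.
    """
    peakset = PeakSet(fdr_thresh=fdr_thresh)
    for effect in profile.table["effect"].unique():
        sub = profile.for_effect(effect)
        sig = (sub["empirical_fdr"] <= fdr_thresh).to_numpy()
        peaks: list[Peak] = []
        i = 0
        while i < len(sub):
            if not sig[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(sub) and sig[j + 1]:
                j += 1
            run = sub.iloc[i : j + 1]
            best = run["percent_altered"].max()
            apex_row = run[run["percent_altered"] == best].sort_values(
                "representative_age"
            ).iloc[0]
            peaks.append(
                Peak(
                    effect=effect,
                    start_center=int(run["center_year"].iloc[0]),
                    end_center=int(run["center_year"].iloc[-1]),
                    start_age=float(run["representative_age"].iloc[0]),
                    end_age=float(run["representative_age"].iloc[-1]),
                    apex_center=int(apex_row["center_year"]),
                    apex_age=float(apex_row["representative_age"]),
                    apex_percent=float(apex_row["percent_altered"]),
                    centers=tuple(int(c) for c in run["center_year"]),
                )
            )
            i = j + 1
        if peaks:
            peakset.peaks[effect] = peaks
        if results is not None:
            for peak in peaks:
                sub_r = results.table
                apex = sub_r[
                    (sub_r["effect"] == effect)
                    & (sub_r["center_year"] == peak.apex_center)
                    & sub_r["p"].notna()
                ]
                peakset.apex_genes[(effect, peak.apex_center)] = (
                    apex.sort_values(["p", "gene"]).reset_index(drop=True)
                )
    return peakset


def geneset_fisher_profile(
    results: WindowedEffectResults,
    user_set,
    p_thresh: float = 0.01,
    effect: str = "Age",
) -> pd.DataFrame:
    """Fisher-test enrichment of a user gene set in altered genes per window.

    For each window the 2x2 table crosses membership in the user set
    with alteration at ``p_thresh``; the background is every gene tested
    in that window.  Returns two-sided Fisher p and the conditional-MLE
    odds ratio per window.
    """
    user_set = list(dict.fromkeys(user_set))
    tested_all = set(results.table["gene"].unique())
    matched = [g for g in user_set if g in tested_all]
    if not matched:
        raise ValueError(
            f"no user-set gene matches tested genes; unmatched: {sorted(user_set)}"
        )
    matched_set = set(matched)
    rows = []
    sub_e = results.table[results.table["effect"] == effect]
    for center, sub in sub_e.groupby("center_year", sort=True):
        sub = sub[sub["p"].notna()]
        if sub.empty:
            continue
        in_set = sub["gene"].isin(matched_set).to_numpy()
        altered = (sub["p"] <= p_thresh).to_numpy()
        a = int(np.sum(in_set & altered))
        b = int(np.sum(in_set & ~altered))
        c = int(np.sum(~in_set & altered))
        d = int(np.sum(~in_set & ~altered))
        table = [[a, b], [c, d]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        or_cmle = _odds_ratio(table, kind="conditional").statistic
        rows.append(
            {
                "center_year": center,
                "representative_age": float(sub["representative_age"].iloc[0]),
                "effect": effect,
                "n_set_altered": a,
                "n_set": a + b,
                "n_altered": a + c,
                "n_background": a + b + c + d,
                "odds_ratio": float(or_cmle),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)
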