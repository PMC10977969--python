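"""ShARP-LM core: tapered sliding-window schedule, per-window linear
models for Age, Sex and their interaction, and empirical-Bayes moderated
t-statistics.

For each age window the model per gene is

    GE ~ E0 + alpha * Age_c + beta * Sex_c + chi * (Age_c * Sex_c) + eps

with Age and Sex centered within the window (sex coded female=0, male=1
before centering) and the interaction the elementwise product of the two
centered columns.  Gene-wise residual variances are shrunk toward a
scaled inverse-chi-square prior fitted across genes by the closed-form
method of moments on log variances; moderated t-statistics are referred
to a t distribution with df + d0 degrees of freedom.

Windows span 16 years in the interior of the age range and taper to 11
years at the edges, shifting through consecutive integer years of age.
Each window's results are reported at its representative age, the mean
donor age of its members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import LogExpressionMatrix, SampleTable

logger = logging.getLogger("sharplm")

EFFECTS = ("Age", "Sex", "AgeSex")

__all__ = [
    "EFFECTS",
    "Window",
    "WindowSchedule",
    "WindowedEffectResults",
    "FullRangeFit",
    "build_window_schedule",
    "build_design",
    "fit_window_model",
    "moderate",
    "run_sharplm",
    "fit_full_range",
    "trigamma_inverse",
]


@dataclass(frozen=True)
class Window:
    center: int
    span: float
    lower: float
    upper: float
    sample_ids: tuple[str, ...]
    representative_age: float

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass
class WindowSchedule:
    """Ordered tapered windows over consecutive integer years of age."""

    windows: list[Window]
    span_min: float = 11.0
    span_max: float = 16.0

    def __post_init__(self) -> None:
        for w in self.windows:
            if not (self.span_min <= w.span <= self.span_max):
                raise ValueError(f"window span {w.span} outside [{self.span_min}, {self.span_max}]")
            if not (w.lower <= w.representative_age <= w.upper):
                raise ValueError("representative age outside window interval")

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "center_year": [w.center for w in self.windows],
                "span": [w.span for w in self.windows],
                "lower": [w.lower for w in self.windows],
                "upper": [w.upper for w in self.windows],
                "n_samples": [w.n for w in self.windows],
                "representative_age": [w.representative_age for w in self.windows],
            }
        )


def build_window_schedule(
    samples: SampleTable,
    span_max: float = 16.0,
    span_min: float = 11.0,
    step: int = 1,
    min_window_n: int = 6,
) -> WindowSchedule:
    """Build the tapered sliding-window schedule from donor ages.

    Centers run through consecutive integer years from ceil(min age) to
    floor(max age).  The span grows from ``span_min`` at the edges to
    ``span_max`` in the interior: span(c) = min(span_max, span_min +
    (c - first), span_min + (last - c)).  The window interval
    [c - span/2, c + span/2] is closed at both ends, so a donor exactly
    on a boundary belongs to both adjacent windows.  Windows with fewer
    than ``min_window_n`` members are dropped with a warning.
    """
    ages = samples.age.to_numpy(dtype=float)
    if ages.max() - ages.min() < span_min:
        raise ValueError(
            f"age range {ages.min():.1f}-{ages.max():.1f} narrower than span_min={span_min}"
        )
    first = int(np.ceil(ages.min()))
    last = int(np.floor(ages.max()))
    windows: list[Window] = []
    for center in range(first, last + 1, step):
        span = min(span_max, span_min + (center - first), span_min + (last - center))
        lower = center - span / 2.0
        upper = center + span / 2.0
        member = (ages >= lower) & (ages <= upper)
        ids = tuple(samples.sample_ids[member])
        if len(ids) < min_window_n:
            logger.warning(
                "window center %d: %d samples < min_window_n=%d, dropped",
                center, len(ids), min_window_n,
            )
            continue
        windows.append(
            Window(center, span, lower, upper, ids, float(ages[member].mean()))
        )
    if not windows:
        raise ValueError("no window satisfies the minimum sample requirement")
    return WindowSchedule(windows, span_min=span_min, span_max=span_max)


@dataclass
class Design:
    """Design matrix for one window plus the effect -> column mapping."""

    matrix: np.ndarray
    columns: list[str]
    effect_cols: dict[str, int]
    dropped_effects: tuple[str, ...] = ()


def build_design(ages: np.ndarray, sexes: np.ndarray) -> Design:
    """[1, Age_c, Sex_c, Age_c*Sex_c] with within-window centering.

    ``sexes`` holds the labels 'female'/'male'; sex is coded female=0,
    male=1 before centering.  In a sex-constant window the Sex and
    AgeSex columns are dropped and the corresponding effects flagged
    missing.  Raises if age is constant or the fit would be saturated.
    """
    ages = np.asarray(ages, dtype=float)
    if np.ptp(ages) == 0:
        raise ValueError("age constant within window; model unusable")
    age_c = ages - ages.mean()
    sex_code = np.asarray([1.0 if s == "male" else 0.0 for s in sexes])
    if np.ptp(sex_code) == 0:
        x = np.column_stack([np.ones_like(age_c), age_c])
        design = Design(
            x, ["intercept", "Age"], {"Age": 1}, dropped_effects=("Sex", "AgeSex")
        )
    else:
        sex_c = sex_code - sex_code.mean()
        x = np.column_stack([np.ones_like(age_c), age_c, sex_c, age_c * sex_c])
        design = Design(
            x,
            ["intercept", "Age", "Sex", "AgeSex"],
            {"Age": 1, "Sex": 2, "AgeSex": 3},
        )
    if x.shape[0] < x.shape[1]:
        raise ValueError(
            f"window has {x.shape[0]} samples for {x.shape[1]} coefficients; unusable"
        )
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient window design; unusable")
    return design


@dataclass
class WindowFit:
    """Gene-wise least-squares fit of one window's design."""

    coef: np.ndarray           # genes x p
    sigma2: np.ndarray         # genes, residual variance RSS/df
    stdev_unscaled: np.ndarray # p, sqrt(diag((X'X)^-1))
    df: int
    design: Design
    gene_ids: pd.Index


def fit_window_model(y: np.ndarray, design: Design, gene_ids: pd.Index) -> WindowFit:
    """Ordinary least squares for all genes at once.

    ``y`` is genes x samples; coefficients solve the normal equations,
    residual variance is RSS / (n - p), and the unscaled standard errors
    come from the diagonal of the inverted Gram matrix.
    """
    x = design.matrix
    n, p = x.shape
    df = n - p
    if df < 1:
        raise ValueError("zero residual degrees of freedom; window unusable")
    xtx_inv = np.linalg.inv(x.T @ x)
    coef = y @ x @ xtx_inv.T  # genes x p
    resid = y - coef @ x.T
    rss = np.einsum("ij,ij->i", resid, resid)
    sigma2 = rss / df
    stdev_unscaled = np.sqrt(np.diag(xtx_inv))
    return WindowFit(coef, sigma2, stdev_unscaled, df, design, gene_ids)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-8:
            break
    return float(x)


@dataclass
class Moderation:
    """Empirical-Bayes shrinkage output for one window."""

    d0: float                  # prior degrees of freedom
    s0_2: float                # prior variance
    post_var: np.ndarray       # genes, posterior residual variance
    t: np.ndarray              # genes x p moderated t
    p: np.ndarray              # genes x p two-sided p-values
    ordinary: bool = False     # True when the ordinary-t fallback fired


def _fit_variance_prior(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square prior.

    Works on log variances: with z = log(s^2) and e = z - digamma(df/2)
    + log(df/2), the excess variance of e over trigamma(df/2) identifies
    d0 through the trigamma function, and its mean identifies s0^2.
    """
    z = np.log(sigma2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess variability across genes: infinite prior df; the
        # bias-correction terms are evaluated at the residual df
        d0 = np.inf
        s0_2 = float(np.exp(emean + special.digamma(df / 2.0) - np.log(df / 2.0)))
    return d0, s0_2


def moderate(fit: WindowFit, min_genes: int = 10) -> Moderation:
    """Moderated t and p per effect by empirical-Bayes variance shrinkage.

    Posterior variance per gene is (d0*s0^2 + df*s^2) / (d0 + df); the
    moderated t divides each coefficient by sqrt(posterior variance)
    times the unscaled standard error, with df + d0 degrees of freedom.
    With fewer than ``min_genes`` genes, or all residual variances zero,
    the ordinary t-test is used with a warning.  Genes with zero residual
    variance take the prior variance s0^2 for stability.
    """
    sigma2 = fit.sigma2.copy()
    positive = sigma2 > 0
    if fit.coef.shape[0] < min_genes or not positive.any():
        if not positive.any():
            logger.warning("moderate: all residual variances zero; ordinary t fallback")
        else:
            logger.warning(
                "moderate: only %d genes; ordinary t fallback", fit.coef.shape[0]
            )
        se = np.sqrt(np.maximum(sigma2, np.finfo(float).tiny))[:, None] * fit.stdev_unscaled
        t = fit.coef / se
        p = 2.0 * stats.t.sf(np.abs(t), fit.df)
        return Moderation(0.0, float(np.median(sigma2)), sigma2, t, p, ordinary=True)

    d0, s0_2 = _fit_variance_prior(sigma2[positive], fit.df)
    sigma2[~positive] = s0_2
    if (~positive).any():
        logger.warning(
            "moderate: %d zero-variance genes set to prior variance", int((~positive).sum())
        )
    if np.isinf(d0):
        post_var = np.full_like(sigma2, s0_2)
        total_df: float = np.inf
    else:
        post_var = (d0 * s0_2 + fit.df * sigma2) / (d0 + fit.df)
        total_df = fit.df + d0
    se = np.sqrt(post_var)[:, None] * fit.stdev_unscaled
    t = fit.coef / se
    p = 2.0 * stats.t.sf(np.abs(t), total_df)
    return Moderation(d0, s0_2, post_var, t, p)


@dataclass
class WindowedEffectResults:
    """Long-format per (gene, window, effect) results plus window metadata.

    ``table`` columns: gene, effect, center_year, representative_age,
    coef, se, t, p.  ``window_info`` carries per-window df, d0, s0^2,
    sample count and usability flags; unusable windows are flagged, never
    silently dropped.
    """

    table: pd.DataFrame
    window_info: pd.DataFrame
    effects: tuple[str, ...] = EFFECTS

    def for_window(self, center: int) -> pd.DataFrame:
        return self.table[self.table["center_year"] == center]

    def pivot_p(self, effect: str) -> pd.DataFrame:
        """genes x windows matrix of p-values for one effect."""
        sub = self.table[self.table["effect"] == effect]
        return sub.pivot(index="gene", columns="center_year", values="p")

    def pivot_t(self, effect: str) -> pd.DataFrame:
        sub = self.table[self.table["effect"] == effect]
        return sub.pivot(index="gene", columns="center_year", values="t")


def _window_results_rows(
    fit: WindowFit, mod: Moderation, window: Window
) -> pd.DataFrame:
    frames = []
    for effect in EFFECTS:
        if effect in fit.design.effect_cols:
            j = fit.design.effect_cols[effect]
            se = np.sqrt(mod.post_var) * fit.stdev_unscaled[j]
            frames.append(
                pd.DataFrame(
                    {
                        "gene": fit.gene_ids,
                        "effect": effect,
                        "center_year": window.center,
                        "representative_age": window.representative_age,
                        "coef": fit.coef[:, j],
                        "se": se,
                        "t": mod.t[:, j],
                        "p": mod.p[:, j],
                    }
                )
            )
        else:
            frames.append(
                pd.DataFrame(
                    {
                        "gene": fit.gene_ids,
                        "effect": effect,
                        "center_year": window.center,
                        "representative_age": window.representative_age,
                        "coef": np.nan,
                        "se": np.nan,
                        "t": np.nan,
                        "p": np.nan,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def run_sharplm(
    expr: LogExpressionMatrix,
    samples: SampleTable,
    schedule: WindowSchedule | None = None,
    min_genes_moderation: int = 10,
) -> WindowedEffectResults:
    """Fit and moderate every window; concatenate long-format results.

    Each window is tagged with its representative age (mean donor age of
    its members).  Windows whose design cannot be fitted are flagged in
    ``window_info`` with the failure reason and contribute no rows.
    """
    if schedule is None:
        schedule = build_window_schedule(samples)
    meta = samples.table
    y_all = expr.values
    frames = []
    info_rows = []
    for window in schedule:
        ids = list(window.sample_ids)
        info = {
            "center_year": window.center,
            "span": window.span,
            "n_samples": window.n,
            "representative_age": window.representative_age,
            "usable": True,
            "reason": "",
            "df": np.nan,
            "d0": np.nan,
            "s0_2": np.nan,
        }
        try:
            design = build_design(
                meta.loc[ids, "age"].to_numpy(),
                meta.loc[ids, "sex"].to_numpy(),
            )
            fit = fit_window_model(
                y_all[ids].to_numpy(dtype=float), design, expr.gene_ids
            )
            mod = moderate(fit, min_genes=min_genes_moderation)
        except ValueError as exc:
            logger.warning("window center %d unusable: %s", window.center, exc)
            info["usable"] = False
            info["reason"] = str(exc)
            info_rows.append(info)
            continue
        info["df"] = fit.df
        info["d0"] = mod.d0
        info["s0_2"] = mod.s0_2
        info_rows.append(info)
        frames.append(_window_results_rows(fit, mod, window))
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["gene", "effect", "center_year", "representative_age",
                     "coef", "se", "t", "p"]
        )
    )
    return WindowedEffectResults(table, pd.DataFrame(info_rows))


@dataclass
class FullRangeFit:
    """Whole-age-range linear model per gene (same design construction).

    The Age coefficient is the log2 fold change per year of age.
    """

    table: pd.DataFrame  # gene, effect, coef, t, p


def fit_full_range(expr: LogExpressionMatrix, samples: SampleTable) -> FullRangeFit:
    ages = samples.age.to_numpy()
    if len(ages) < 10:
        raise ValueError("need at least 10 samples for the full-range model")
    if np.ptp(ages) < 10:
        raise ValueError("need an age span of at least 10 years")
    design = build_design(ages, samples.sex.to_numpy())
    y = expr.values[list(samples.sample_ids)].to_numpy(dtype=float)
    fit = fit_window_model(y, design, expr.gene_ids)
    mod = moderate(fit)
    frames = []
    for effect in EFFECTS:
        if effect not in design.effect_cols:
            continue
        j = design.effect_cols[effect]
        frames.append(
            pd.DataFrame(
                {
                    "gene": expr.gene_ids,
                    "effect": effect,
                    "coef": fit.coef[:, j],
                    "t": mod.t[:, j],
                    "p": mod.p[:, j],
                }
            )
        )
    return FullRangeFit(pd.concat(frames, ignore_index=True))
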