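"""Preranked gene-set enrichment over age windows.

Genes are ranked by their moderated t-statistic (most positive first)
within a window and effect.  The enrichment score (ES) of a set is the
extremum of the classic weighted Kolmogorov-Smirnov running sum (hit
increments proportional to |t|^w with w = 1, uniform miss decrements).
The null distribution comes from size-matched random gene sets drawn
from the ranked universe; the normalized enrichment score is

    NES = ES / mean(|null ES| of the same sign)

and the nominal p-value is the +1-smoothed one-sided tail fraction among
same-sign null scores, Benjamini-Hochberg adjusted across sets within
the window.  Reporting follows the pipeline's filters: sets of 15-500
genes after intersection with the universe, adjusted p <= 0.05 within a
significant age peak, narrowed to the top 1% of adjusted p-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneSetCollection
from .profiles import PeakSet
from .windows import WindowedEffectResults

logger = logging.getLogger("sharplm")

__all__ = [
    "rank_genes",
    "enrichment_score",
    "gsea",
    "gsea_all_windows",
    "filter_gsea_results",
]


def rank_genes(
    results: WindowedEffectResults, window_center: int, effect: str = "Age"
) -> pd.Series:
    """Moderated t-statistics sorted descending; ties broken by gene id.

    Returns a Series indexed by gene, ordered from the most positive to
    the most negative statistic.  Requires at least 100 ranked genes.
    """
    sub = results.table[
        (results.table["center_year"] == window_center)
        & (results.table["effect"] == effect)
    ]
    sub = sub[sub["t"].notna()]
    if len(sub) < 100:
        raise ValueError(
            f"only {len(sub)} genes with a statistic in window {window_center}; need >= 100"
        )
    sub = sub.sort_values(["t", "gene"], ascending=[False, True], kind="mergesort")
    return pd.Series(sub["t"].to_numpy(), index=sub["gene"].to_numpy(), name="t")


def enrichment_score(
    ranking: pd.Series, genes, weight: float = 1.0
) -> tuple[float, list[str]]:
    """ES of a gene set in a ranked list, plus the leading edge.

    The running sum increments by |t_i|^w / sum_hits |t|^w at each hit
    and decrements by 1/(N - N_hits) at each miss; the ES is the value
    of maximal absolute deviation from zero.  The leading edge is the
    hits up to and including the extremum for a positive ES, and the
    hits at or after the extremum for a negative ES.
    """
    gene_ids = np.asarray(ranking.index)
    stat = ranking.to_numpy(dtype=float)
    hit = np.isin(gene_ids, list(set(genes)))
    if not hit.any():
        raise ValueError("gene set has no overlap with the ranking")
    if hit.all():
        raise ValueError("gene set covers all ranked genes; misses undefined")
    es, idx = _es_from_hits(stat, hit, weight)
    if es >= 0:
        leading = gene_ids[: idx + 1][hit[: idx + 1]]
    else:
        leading = gene_ids[idx:][hit[idx:]]
    return es, [str(g) for g in leading]


def _es_from_hits(stat: np.ndarray, hit: np.ndarray, weight: float) -> tuple[float, int]:
    """Extremum of the weighted KS running sum and its position."""
    n = stat.size
    n_hits = int(hit.sum())
    w = np.abs(stat) ** weight
    hit_total = w[hit].sum()
    if hit_total == 0:
        # all hit statistics exactly zero: fall back to unweighted hits
        increments = np.where(hit, 1.0 / n_hits, 0.0)
    else:
        increments = np.where(hit, w / hit_total, 0.0)
    decrement = 1.0 / (n - n_hits)
    steps = increments - np.where(hit, 0.0, decrement)
    running = np.cumsum(steps)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), idx


@dataclass
class GseaResult:
    """Per (set, window, effect) enrichment table."""

    table: pd.DataFrame  # set, window, effect, size, es, nes, p, padj, leading_edge


def gsea(
    results: WindowedEffectResults,
    collection: GeneSetCollection,
    window_center: int,
    effect: str = "Age",
    n_null: int = 10_000,
    seed: int = 1,
    min_size: int = 15,
    max_size: int = 500,
    weight: float = 1.0,
) -> GseaResult:
    """Preranked GSEA of every eligible set in one window.

    Sets are pre-filtered to ``min_size <= |set ∩ universe| <= max_size``.
    Null ES values come from ``n_null`` random same-size draws from the
    universe; NES and nominal p are computed against same-sign nulls and
    p-values BH-adjusted across sets within the window.
    """
    ranking = rank_genes(results, window_center, effect)
    universe = np.asarray(ranking.index)
    rng = np.random.default_rng(seed)
    rows = []
    for gs in collection:
        members = set(gs.genes) & set(universe)
        size = len(members)
        if not (min_size <= size <= max_size):
            continue
        es, leading = enrichment_score(ranking, members, weight=weight)
        stat = ranking.to_numpy(dtype=float)
        n_univ = len(universe)
        null_es = np.empty(n_null)
        for k in range(n_null):
            hit = np.zeros(n_univ, dtype=bool)
            hit[rng.choice(n_univ, size=size, replace=False)] = True
            null_es[k], _ = _es_from_hits(stat, hit, weight)
        same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        if len(same_sign) == 0:
            nes = np.nan
            p = 1.0 / (n_null + 1.0)
            logger.warning(
                "gsea: no same-sign null ES for set %r; p floored", gs.name
            )
        else:
            nes = es / np.mean(np.abs(same_sign))
            p = (1.0 + np.sum(np.abs(same_sign) >= abs(es))) / (1.0 + len(same_sign))
        rows.append(
            {
                "set": gs.name,
                "source": gs.source,
                "center_year": window_center,
                "effect": effect,
                "size": size,
                "es": es,
                "nes": nes,
                "p": p,
                "leading_edge": ",".join(leading),
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["padj"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["padj"] = pd.Series(dtype=float)
    cols = ["set", "source", "center_year", "effect", "size", "es", "nes",
            "p", "padj", "leading_edge"]
    return GseaResult(table[cols] if not table.empty else pd.DataFrame(columns=cols))


def gsea_all_windows(
    results: WindowedEffectResults,
    collection: GeneSetCollection,
    effect: str = "Age",
    centers=None,
    **kwargs,
) -> GseaResult:
    """Run :func:`gsea` over multiple window centers and concatenate."""
    if centers is None:
        centers = sorted(results.table["center_year"].unique())
    frames = []
    seed = kwargs.pop("seed", 1)
    for i, center in enumerate(centers):
        frames.append(
            gsea(results, collection, int(center), effect=effect,
                 seed=seed + i, **kwargs).table
        )
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return GseaResult(table)


def filter_gsea_results(
    gsea_results: GseaResult,
    peaks: PeakSet,
    padj_thresh: float = 0.05,
    top_fraction: float = 0.01,
) -> GseaResult:
    """Apply the pipeline's reporting filters to cross-window GSEA results.

    A set is reported when its adjusted p is <= ``padj_thresh`` in at
    least one window belonging to a significant age peak, and its best
    such adjusted p ranks within the top ``top_fraction`` of all sets
    (per effect): ceil(top_fraction * n_sets) sets at most.
    """
    table = gsea_results.table
    if table.empty or len(peaks) == 0:
        return GseaResult(table.iloc[0:0])
    kept_frames = []
    for effect, sub in table.groupby("effect"):
        eligible_centers = peaks.peak_centers(effect)
        in_peak = sub[sub["center_year"].isin(eligible_centers)]
        sig = in_peak[in_peak["padj"] <= padj_thresh]
        if sig.empty:
            continue
        best = sig.groupby("set")["padj"].min().sort_values(kind="mergesort")
        n_sets = sub["set"].nunique()
        n_keep = max(1, math.ceil(top_fraction * n_sets))
        keep_sets = set(best.index[:n_keep])
        kept_frames.append(
            sub[sub["set"].isin(keep_sets) & sub["center_year"].isin(eligible_centers)]
        )
    if not kept_frames:
        return GseaResult(table.iloc[0:0])
    return GseaResult(pd.concat(kept_frames, ignore_index=True))
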