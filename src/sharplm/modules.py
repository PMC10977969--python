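"""Weighted co-expression modules: variance filter, biweight
midcorrelation, soft thresholding, topological overlap, static tree cut,
eigengenes and Fisher enrichment against cell-type / disease signatures.

The network is unsigned: adjacency a_ij = |bicor_ij|^soft_power (default
power 12).  Topological overlap counts shared neighbours,

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

and modules are branches of the average-linkage dendrogram of 1 - TOM
cut at a fixed height, kept when they hold at least ``min_module_size``
genes.  Each module is summarized by its eigengene — the first right
singular vector of the standardized module submatrix — oriented to
correlate positively with the module's mean profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats.contingency import odds_ratio as _odds_ratio
from statsmodels.stats.multitest import multipletests

from .datatypes import LogExpressionMatrix, SampleTable

logger = logging.getLogger("sharplm")

__all__ = [
    "CoexpressionConfig",
    "CoexpressionModule",
    "TISSUE_CONFIGS",
    "select_variable_genes",
    "bicor_matrix",
    "scale_free_fit",
    "tom_similarity",
    "detect_modules",
    "module_eigengene",
    "module_enrichment",
    "eigengene_age_profile",
    "detect_coexpression_modules",
]


@dataclass(frozen=True)
class CoexpressionConfig:
    """Tuning knobs of the module pipeline.

    variance_threshold — minimum across-sample variance for a gene to
    enter the network; min_module_size — smallest branch kept as a
    module; cut_height — static tree-cut height on the 1 - TOM
    dendrogram; soft_power — exponent of the soft threshold.
    """

    variance_threshold: float = 0.5
    min_module_size: int = 15
    cut_height: float = 0.95
    soft_power: float = 12.0

    def __post_init__(self) -> None:
        if self.variance_threshold < 0:
            raise ValueError("variance_threshold must be >= 0")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not (0 < self.cut_height < 1):
            raise ValueError("cut_height must be in (0, 1)")
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")


# per-tissue defaults shipped with the pipeline (variance threshold,
# min module size, cut height, soft power)
TISSUE_CONFIGS: dict[str, CoexpressionConfig] = {
    "brain_cortex": CoexpressionConfig(0.5, 15, 0.95, 12.0),
    "heart_left_ventricle": CoexpressionConfig(0.4, 20, 0.98, 12.0),
    "lung": CoexpressionConfig(0.35, 20, 0.99, 12.0),
    "skeletal_muscle": CoexpressionConfig(0.9, 15, 0.97, 12.0),
}


def select_variable_genes(
    expr: LogExpressionMatrix, variance_threshold: float, min_module_size: int = 15
) -> list[str]:
    """Genes whose across-sample variance is >= the threshold (inclusive)."""
    if variance_threshold < 0:
        raise ValueError("variance_threshold must be >= 0")
    var = expr.values.var(axis=1, ddof=1)
    keep = var.index[var >= variance_threshold].tolist()
    if len(keep) < 2 * min_module_size:
        raise ValueError(
            f"only {len(keep)} genes pass the variance filter; "
            f"need at least {2 * min_module_size}"
        )
    return keep


def bicor_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Biweight midcorrelation between all gene pairs (genes x samples in).

    Each gene is median-centered and its deviations weighted by
    (1 - u^2)^2 for |u| < 1 with u = deviation / (9 * MAD).  Genes with
    zero MAD fall back to Pearson for all their pairs, with a warning.
    """
    mat = values.to_numpy(dtype=float)
    n_genes, n_samples = mat.shape
    if n_samples < 5:
        raise ValueError("need at least 5 samples for biweight midcorrelation")
    med = np.median(mat, axis=1, keepdims=True)
    dev = mat - med
    mad = np.median(np.abs(dev), axis=1, keepdims=True)
    zero_mad = mad.ravel() == 0
    if zero_mad.any():
        logger.warning(
            "bicor_matrix: %d genes with zero MAD fall back to Pearson",
            int(zero_mad.sum()),
        )
    safe_mad = np.where(mad == 0, 1.0, mad)
    u = dev / (9.0 * safe_mad)
    w = np.square(1.0 - np.square(u)) * (np.abs(u) < 1.0)
    x = dev * w

    def _row_normalize(m):
        norms = np.sqrt(np.einsum("ij,ij->i", m, m))
        norms[norms == 0] = 1.0  # constant genes: correlation 0 everywhere
        return m / norms[:, None]

    xn = _row_normalize(x)
    corr = xn @ xn.T
    if zero_mad.any():
        # pairs involving a zero-MAD gene use plain Pearson on both sides
        pn = _row_normalize(mat - mat.mean(axis=1, keepdims=True))
        pearson = pn @ pn.T
        corr[zero_mad, :] = pearson[zero_mad, :]
        corr[:, zero_mad] = pearson[:, zero_mad]
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(corr, index=values.index, columns=values.index)


def scale_free_fit(
    correlations: pd.DataFrame, powers=(1, 2, 4, 6, 8, 10, 12, 14, 16), n_bins: int = 10
) -> pd.DataFrame:
    """Scale-free-topology fit index per candidate soft power.

    For each power, connectivity k_i = sum_j |cor_ij|^power (j != i); the
    k values are binned into ``n_bins`` equal-width bins (empty bins
    dropped) and R^2 of log10(frequency) on log10(mean k per bin) is
    reported along with the regression slope.  A scale-free network
    shows high R^2 with a negative slope.  Degenerate connectivity (all
    equal) is reported as missing.
    """
    mat = np.abs(correlations.to_numpy(dtype=float))
    np.fill_diagonal(mat, 0.0)
    rows = []
    for power in powers:
        k = (mat ** power).sum(axis=1)
        if np.ptp(k) == 0:
            rows.append({"power": power, "r_squared": np.nan, "slope": np.nan})
            continue
        edges = np.linspace(k.min(), k.max(), n_bins + 1)
        which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
        means, freqs = [], []
        for b in range(n_bins):
            in_bin = which == b
            if in_bin.sum() == 0:
                continue
            mk = k[in_bin].mean()
            if mk <= 0:
                continue
            means.append(mk)
            freqs.append(in_bin.mean())
        if len(means) < 3:
            rows.append({"power": power, "r_squared": np.nan, "slope": np.nan})
            continue
        lx, ly = np.log10(means), np.log10(freqs)
        slope, _, r, _, _ = stats.linregress(lx, ly)
        rows.append({"power": power, "r_squared": float(r ** 2), "slope": float(slope)})
    return pd.DataFrame(rows)


def tom_similarity(correlations: pd.DataFrame, soft_power: float = 12.0) -> pd.DataFrame:
    """Topological overlap matrix of the unsigned soft-thresholded network.

    a_ij = |cor_ij|^soft_power with zero self-adjacency; TOM_ij =
    (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), TOM_ii = 1.
    Values are in [0, 1] and symmetric (asserted).
    """
    a = np.abs(correlations.to_numpy(dtype=float)) ** soft_power
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    assert np.allclose(tom, tom.T)
    return pd.DataFrame(tom, index=correlations.index, columns=correlations.columns)


def detect_modules(
    dissimilarity: pd.DataFrame,
    min_module_size: int = 15,
    cut_height: float = 0.95,
    method: str = "average",
) -> pd.Series:
    """Static tree cut of the dissimilarity dendrogram into modules.

    Branches obtained by cutting the ``method``-linkage tree at
    ``cut_height`` become modules when they hold at least
    ``min_module_size`` genes, labelled "module1", "module2", ... by
    decreasing size (ties by youngest member gene id); everything else
    is "unassigned".
    """
    genes = dissimilarity.index
    d = dissimilarity.to_numpy(dtype=float)
    condensed = squareform((d + d.T) / 2.0, checks=False)
    z = linkage(condensed, method=method)
    branch = fcluster(z, t=cut_height, criterion="distance")
    labels = pd.Series("unassigned", index=genes, dtype=object)
    sizes = pd.Series(branch).value_counts()
    big = sizes[sizes >= min_module_size]
    if big.empty:
        logger.warning("detect_modules: no branch reaches min_module_size=%d",
                       min_module_size)
        return labels
    # order branches by size desc, tie-break by first member gene id
    order = sorted(
        big.index,
        key=lambda b: (-int(big[b]), str(min(genes[branch == b]))),
    )
    for rank, b in enumerate(order, start=1):
        labels[branch == b] = f"module{rank}"
    return labels


def module_eigengene(values: pd.DataFrame) -> tuple[pd.Series, float]:
    """Eigengene and variance explained of one module submatrix.

    Genes (rows) are standardized across samples; the eigengene is the
    first right singular vector of the standardized genes x samples
    matrix, unit norm, sign-oriented to correlate positively with the
    module's mean standardized profile.  Zero-variance genes are dropped
    with a warning before the decomposition.
    """
    if values.shape[0] < 2:
        raise ValueError("module needs at least 2 genes")
    mat = values.to_numpy(dtype=float)
    sd = mat.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning(
            "module_eigengene: dropping %d zero-variance genes", int((~keep).sum())
        )
        mat = mat[keep]
        sd = sd[keep]
    if mat.shape[0] < 2:
        raise ValueError("fewer than 2 non-constant genes in module")
    std = (mat - mat.mean(axis=1, keepdims=True)) / sd[:, None]
    u, s, vt = np.linalg.svd(std, full_matrices=False)
    eig = vt[0]
    mean_profile = std.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    variance_explained = float(s[0] ** 2 / np.sum(s ** 2))
    return pd.Series(eig, index=values.columns, name="eigengene"), variance_explained


@dataclass
class CoexpressionModule:
    """One detected module: members, eigengene, enrichments."""

    label: str
    genes: list[str]
    eigengene: pd.Series
    variance_explained: float
    enrichments: pd.DataFrame | None = None


def module_enrichment(
    modules: dict[str, list[str]],
    signatures: dict[str, list[str]],
    background: list[str],
) -> pd.DataFrame:
    """Fisher enrichment of each module in each signature.

    The 2x2 table crosses module membership with signature membership
    within ``background`` (the genes entering module definition);
    signatures with no background overlap are skipped with a warning.
    BH adjustment runs across signatures within each module; a hit is
    flagged significant when OR > 1 and p < 0.05.
    """
    bg = list(dict.fromkeys(background))
    bg_set = set(bg)
    rows = []
    for mod_label, mod_genes in modules.items():
        mod_set = set(mod_genes) & bg_set
        mod_rows = []
        for sig_label, sig_genes in signatures.items():
            sig_set = set(sig_genes) & bg_set
            if not sig_set:
                logger.warning(
                    "module_enrichment: signature %r has no background overlap; skipped",
                    sig_label,
                )
                continue
            a = len(mod_set & sig_set)
            b = len(mod_set - sig_set)
            c = len(sig_set - mod_set)
            d = len(bg_set) - a - b - c
            table = [[a, b], [c, d]]
            _, p = stats.fisher_exact(table, alternative="two-sided")
            or_cmle = _odds_ratio(table, kind="conditional").statistic
            mod_rows.append(
                {
                    "module": mod_label,
                    "signature": sig_label,
                    "n_overlap": a,
                    "odds_ratio": float(or_cmle),
                    "p_value": float(p),
                }
            )
        if mod_rows:
            sub = pd.DataFrame(mod_rows)
            sub["padj"] = multipletests(sub["p_value"], method="fdr_bh")[1]
            sub["significant"] = (sub["odds_ratio"] > 1) & (sub["p_value"] < 0.05)
            rows.append(sub)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["module", "signature", "n_overlap", "odds_ratio",
                 "p_value", "padj", "significant"]
    )


def eigengene_age_profile(
    modules: dict[str, CoexpressionModule], samples: SampleTable
) -> pd.DataFrame:
    """Centered/scaled eigengene trends with samples ordered by age.

    One row per (module, sample); a constant eigengene yields an
    all-zero trend (flagged by the zero-variance guard).
    """
    order = samples.table.sort_values("age").index
    frames = []
    for label, mod in modules.items():
        eig = mod.eigengene.reindex(order)
        sd = eig.std(ddof=1)
        scaled = (eig - eig.mean()) / sd if sd > 0 else eig * 0.0
        if sd == 0:
            logger.warning("eigengene_age_profile: module %r eigengene constant", label)
        frames.append(
            pd.DataFrame(
                {
                    "module": label,
                    "sample_id": order,
                    "age": samples.table.loc[order, "age"].to_numpy(),
                    "eigengene_scaled": scaled.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["module", "sample_id", "age", "eigengene_scaled"]
    )


def detect_coexpression_modules(
    expr: LogExpressionMatrix,
    config: CoexpressionConfig = CoexpressionConfig(),
    signatures: dict[str, list[str]] | None = None,
    linkage_method: str = "average",
) -> dict[str, CoexpressionModule]:
    """Full module pipeline: filter, bicor, TOM, tree cut, eigengenes,
    optional signature enrichment."""
    genes = select_variable_genes(
        expr, config.variance_threshold, config.min_module_size
    )
    sub = expr.values.loc[genes]
    corr = bicor_matrix(sub)
    tom = tom_similarity(corr, config.soft_power)
    labels = detect_modules(
        1.0 - tom, config.min_module_size, config.cut_height, method=linkage_method
    )
    modules: dict[str, CoexpressionModule] = {}
    for label in sorted(set(labels) - {"unassigned"}, key=lambda s: int(s[6:])):
        members = labels.index[labels == label].tolist()
        eig, ve = module_eigengene(sub.loc[members])
        modules[label] = CoexpressionModule(label, members, eig, ve)
    if signatures and modules:
        enr = module_enrichment(
            {m.label: m.genes for m in modules.values()}, signatures, genes
        )
        for m in modules.values():
            m.enrichments = enr[enr["module"] == m.label].reset_index(drop=True)
    return modules
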