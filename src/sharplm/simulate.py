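"""Seeded generator of GTEx-like synthetic cohorts with known ground truth.

The generator emulates an adult bulk RNA-seq cohort of one tissue: donor
ages on 20-70 (uniform or an older-heavy mixture mimicking post-mortem
tissue banks), two sexes, negative-binomial read counts over log-normal
library sizes, and injected effects with known class per gene:

* ``age`` genes shift smoothly with age following a sigmoid centered at
  an onset age tau, so a local slope exists inside any 11-16-year
  window and windows far from tau show attenuated effects;
* ``sex`` genes carry a mean shift between sexes;
* ``age_sex`` genes age only in one sex (a sex-specific sigmoid);
* ``covariate`` genes track a nuisance covariate (cohort indicator).

Nuisance covariates (cohort, RNA integrity, detected-gene count) are
emitted with the sample table.  Everything is reproducible from the
spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, GeneSet, GeneSetCollection, SampleTable

__all__ = [
    "CohortSpec",
    "SyntheticTruth",
    "generate_cohort",
    "generate_genesets",
    "generate_signatures",
]

EFFECT_CLASSES = ("null", "age", "sex", "age_sex", "covariate")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    Fractions give the proportion of genes per non-null effect class and
    must sum to at most 1.  ``age_distribution`` is "uniform" on
    [age_min, age_max] or "gtex_skewed", an older-heavy mixture.
    Amplitudes are in log2-CPM units; age effects transition over
    ``onset_width`` years around the onset age.
    """

    n_samples: int = 200
    n_genes: int = 2000
    age_distribution: str = "uniform"
    age_min: float = 20.0
    age_max: float = 70.0
    sex_ratio: float = 0.5          # fraction female
    frac_age: float = 0.0
    frac_sex: float = 0.0
    frac_age_sex: float = 0.0
    frac_covariate: float = 0.0
    onset_age: float = 50.0         # tau, years
    onset_width: float = 4.0        # sigmoid scale, years
    amplitude: float = 1.0          # log2-CPM shift at full effect
    nb_dispersion: float = 0.1
    lib_size_mean: float = 1e6
    lib_size_sigma: float = 0.3     # log-normal spread of library sizes
    baseline_log2cpm_mean: float = 4.0
    baseline_log2cpm_sd: float = 1.5
    covariate_amplitude: float = 1.0
    seed: int = 1

    def __post_init__(self) -> None:
        total = self.frac_age + self.frac_sex + self.frac_age_sex + self.frac_covariate
        if total > 1.0 + 1e-12:
            raise ValueError(f"effect-class fractions sum to {total} > 1")
        if any(f < 0 for f in (self.frac_age, self.frac_sex,
                               self.frac_age_sex, self.frac_covariate)):
            raise ValueError("effect-class fractions must be >= 0")
        if self.age_distribution not in ("uniform", "gtex_skewed"):
            raise ValueError(f"unknown age distribution {self.age_distribution!r}")
        if not (self.age_min <= self.onset_age <= self.age_max):
            raise ValueError("onset age outside the cohort age range")
        if self.n_samples < 30:
            raise ValueError("need n_samples >= 30 for windowed analyses")


@dataclass
class SyntheticTruth:
    """Ground truth: per-gene effect class, onset, amplitude, direction."""

    table: pd.DataFrame  # gene, effect_class, onset_age, amplitude, direction

    def genes_of_class(self, effect_class: str) -> list[str]:
        t = self.table
        return t.loc[t["effect_class"] == effect_class, "gene"].tolist()


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _draw_ages(rng: np.random.Generator, spec: CohortSpec) -> np.ndarray:
    if spec.age_distribution == "uniform":
        return rng.uniform(spec.age_min, spec.age_max, spec.n_samples)
    # older-heavy mixture: 30% uniform over the full range, 70%
    # concentrated in the upper half (post-mortem donor demographics)
    mid = (spec.age_min + spec.age_max) / 2.0
    young = rng.uniform(spec.age_min, spec.age_max, spec.n_samples)
    old = rng.uniform(mid, spec.age_max, spec.n_samples)
    pick_old = rng.random(spec.n_samples) < 0.7
    return np.where(pick_old, old, young)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[CountMatrix, SampleTable, SyntheticTruth]:
    """Simulate counts, sample metadata and ground truth for one cohort.

    Baseline per-gene mean expression is drawn log-normally; injected
    effects shift the log2 mean as described in the module docstring;
    counts are negative-binomial around the scaled means with per-sample
    library sizes.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_samples, spec.n_genes

    ages = _draw_ages(rng, spec)
    sexes = np.where(rng.random(n) < spec.sex_ratio, "female", "male")
    cohort = np.where(rng.random(n) < 0.5, "organ_donor", "postmortem")
    rin = np.clip(rng.normal(7.0, 1.0, n), 3.0, 10.0)
    lib_sizes = spec.lib_size_mean * np.exp(
        rng.normal(0.0, spec.lib_size_sigma, n) - spec.lib_size_sigma ** 2 / 2.0
    )

    # assign effect classes in gene order: age, sex, age_sex, covariate, null
    n_age = int(round(spec.frac_age * g))
    n_sex = int(round(spec.frac_sex * g))
    n_age_sex = int(round(spec.frac_age_sex * g))
    n_cov = int(round(spec.frac_covariate * g))
    classes = np.array(
        ["age"] * n_age + ["sex"] * n_sex + ["age_sex"] * n_age_sex
        + ["covariate"] * n_cov + ["null"] * (g - n_age - n_sex - n_age_sex - n_cov)
    )
    rng.shuffle(classes)
    directions = rng.choice([-1.0, 1.0], size=g)

    base_log2cpm = rng.normal(spec.baseline_log2cpm_mean, spec.baseline_log2cpm_sd, g)

    # log2-CPM shift per (gene, sample)
    shift = np.zeros((g, n))
    sex_code = (sexes == "male").astype(float)
    cov_code = (cohort == "organ_donor").astype(float)
    age_curve = _sigmoid((ages - spec.onset_age) / spec.onset_width)
    for i in range(g):
        cls = classes[i]
        amp = spec.amplitude * directions[i]
        if cls == "age":
            shift[i] = amp * age_curve
        elif cls == "sex":
            shift[i] = amp * (sex_code - 0.5)
        elif cls == "age_sex":
            shift[i] = amp * age_curve * sex_code
        elif cls == "covariate":
            shift[i] = spec.covariate_amplitude * directions[i] * cov_code

    log2cpm = base_log2cpm[:, None] + shift
    cpm = 2.0 ** log2cpm
    cpm = cpm / cpm.sum(axis=0, keepdims=True) * 1e6  # renormalize composition
    mean_counts = cpm * (lib_sizes[None, :] / 1e6)

    # NB(mean mu, dispersion phi): var = mu + phi mu^2; gamma-Poisson mixture
    phi = spec.nb_dispersion
    if phi > 0:
        lam = rng.gamma(shape=1.0 / phi, scale=phi * mean_counts)
    else:
        lam = mean_counts
    counts = rng.poisson(lam)

    gene_ids = [f"g{i:05d}" for i in range(g)]
    sample_ids = [f"s{j:04d}" for j in range(n)]
    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids))
    st = SampleTable(
        pd.DataFrame(
            {
                "donor_id": [f"d{j:04d}" for j in range(n)],
                "tissue": "synthetic_tissue",
                "age": ages,
                "sex": sexes,
                "cohort": cohort,
                "rin": rin,
                "n_detected": (counts > 0).sum(axis=0),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = SyntheticTruth(
        pd.DataFrame(
            {
                "gene": gene_ids,
                "effect_class": classes,
                "onset_age": np.where(
                    np.isin(classes, ["age", "age_sex"]), spec.onset_age, np.nan
                ),
                "amplitude": np.where(
                    classes == "null", 0.0,
                    np.where(classes == "covariate",
                             spec.covariate_amplitude, spec.amplitude),
                ),
                "direction": directions,
            }
        )
    )
    return cm, st, truth


def generate_genesets(
    universe,
    n_sets: int = 20,
    size_range: tuple[int, int] = (15, 50),
    planted: dict[str, list[str]] | None = None,
    n_subset_pairs: int = 0,
    seed: int = 1,
    source: str = "synthetic",
) -> GeneSetCollection:
    """Random gene sets over a universe, plus optional planted sets and
    parent/subset pairs for family-clustering tests."""
    universe = list(universe)
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    if lo < 2 or hi >= len(universe) or lo > hi:
        raise ValueError(f"infeasible set sizes {size_range} for universe of "
                         f"{len(universe)} genes")
    coll = GeneSetCollection()
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        genes = rng.choice(universe, size=size, replace=False)
        coll.add(GeneSet(f"random_set_{i:03d}", tuple(str(x) for x in genes),
                         source=source))
    for i in range(n_subset_pairs):
        size = int(rng.integers(max(lo, 4), hi + 1))
        parent = rng.choice(universe, size=size, replace=False)
        child_size = max(2, size // 2)
        child = rng.choice(parent, size=child_size, replace=False)
        coll.add(GeneSet(f"parent_set_{i:03d}", tuple(str(x) for x in parent),
                         source=source))
        coll.add(GeneSet(f"child_set_{i:03d}", tuple(str(x) for x in child),
                         source=source))
    if planted:
        for name, genes in planted.items():
            coll.add(GeneSet(name, tuple(genes), source=source,
                             description="planted"))
    return coll


def generate_signatures(
    module_genes: dict[str, list[str]],
    background,
    purity: float = 1.0,
    size: int | None = None,
    seed: int = 1,
) -> dict[str, list[str]]:
    """Cell-type-like signatures sampling planted module genes at ``purity``.

    Each signature draws round(purity * size) genes from its module and
    the remainder from the background outside the module.
    """
    if not (0 < purity <= 1):
        raise ValueError("purity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    background = list(background)
    out: dict[str, list[str]] = {}
    for label, genes in module_genes.items():
        target = size if size is not None else len(genes)
        n_pure = min(len(genes), int(round(purity * target)))
        picked = list(rng.choice(genes, size=n_pure, replace=False))
        n_noise = target - n_pure
        pool = [x for x in background if x not in set(genes)]
        if n_noise > 0 and pool:
            picked += list(rng.choice(pool, size=min(n_noise, len(pool)),
                                      replace=False))
        out[f"sig_{label}"] = [str(x) for x in picked]
    return out
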