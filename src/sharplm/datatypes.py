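"""Core in-memory containers shared by all pipeline stages.

Expression data travel as a genes x samples table (counts or corrected
log2-CPM), sample annotations as a table indexed by sample id, and gene
sets as named lists with a source label.  All containers validate their
invariants at construction so downstream stages can assume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleTable",
    "GeneSet",
    "GeneSetCollection",
    "LogExpressionMatrix",
]


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer read counts.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows indexed by gene id, columns by sample id.  Entries must be
        non-negative integers (integer-valued floats are accepted and
        cast).

    Attributes
    ----------
    lib_size : pandas.Series
        Per-sample library size, always exactly the column sum.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        dup_g = df.index[df.index.duplicated()].unique().tolist()
        if dup_g:
            raise ValueError(f"duplicate gene ids: {dup_g}")
        dup_s = df.columns[df.columns.duplicated()].unique().tolist()
        if dup_s:
            raise ValueError(f"duplicate sample ids: {dup_s}")
        values = df.to_numpy()
        bad = ~np.isfinite(values.astype(float))
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        if not np.allclose(values, np.round(values.astype(float))):
            frac = ~np.isclose(values, np.round(values.astype(float)))
            g, s = np.argwhere(frac)[0]
            raise ValueError(
                f"non-integer count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        df = df.astype(np.int64)
        df.index = df.index.rename("gene_id")
        df.columns = df.columns.rename(None)
        self.counts = df

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def lib_size(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def cpm(self) -> pd.DataFrame:
        """Counts per million on raw library sizes."""
        lib = self.lib_size.to_numpy(dtype=float)
        if (lib == 0).any():
            zero = self.sample_ids[lib == 0].tolist()
            raise ValueError(f"samples with zero library size: {zero}")
        return self.counts / lib * 1e6

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[genes])

    def subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(self.counts[list(samples)])


REQUIRED_SAMPLE_COLUMNS = ("donor_id", "tissue", "age", "sex")
VALID_SEXES = frozenset({"female", "male"})


@dataclass
class SampleTable:
    """Per-sample annotations: donor, tissue, age in years, sex, covariates.

    ``table`` is indexed by sample id; any column beyond the required four
    is treated as a covariate or condition flag.
    """

    table: pd.DataFrame
    age_range: tuple[float, float] = (18.0, 100.0)

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sample table missing required columns: {missing}")
        dup = df.index[df.index.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate sample ids: {dup}")
        ages = pd.to_numeric(df["age"], errors="coerce")
        if ages.isna().any():
            raise ValueError("non-numeric ages present")
        lo, hi = self.age_range
        out = df.index[(ages < lo) | (ages > hi)].tolist()
        if out:
            raise ValueError(
                f"ages outside plausible range [{lo}, {hi}] for samples: {out}"
            )
        bad_sex = set(df["sex"].unique()) - VALID_SEXES
        if bad_sex:
            raise ValueError(f"unrecognised sex labels: {sorted(bad_sex)}")
        df = df.copy()
        df["age"] = ages.astype(float)
        self.table = df

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def age(self) -> pd.Series:
        return self.table["age"]

    @property
    def sex(self) -> pd.Series:
        return self.table["sex"]

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in REQUIRED_SAMPLE_COLUMNS]

    def subset(self, sample_ids) -> "SampleTable":
        return SampleTable(self.table.loc[list(sample_ids)], self.age_range)

    def for_tissue(self, tissue: str) -> "SampleTable":
        sub = self.table[self.table["tissue"] == tissue]
        if sub.empty:
            raise ValueError(f"no samples for tissue {tissue!r}")
        return SampleTable(sub, self.age_range)


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]
    source: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def as_set(self) -> frozenset:
        return frozenset(self.genes)


@dataclass
class GeneSetCollection:
    """Named gene sets with provenance (source database label)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if name != gs.name:
                raise ValueError(f"key {name!r} does not match set name {gs.name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def add(self, gs: GeneSet) -> None:
        if gs.name in self.sets:
            raise ValueError(f"duplicate gene set name {gs.name!r}")
        self.sets[gs.name] = gs

    def subset(self, names) -> "GeneSetCollection":
        return GeneSetCollection({n: self.sets[n] for n in names})


@dataclass
class LogExpressionMatrix:
    """Genes x samples matrix of (optionally corrected) log2-CPM values.

    ``floor`` records the minimum of the pre-correction matrix so that
    covariate-effect removal can restore it; ``provenance`` lists the
    corrections applied so far.
    """

    values: pd.DataFrame
    provenance: tuple[str, ...] = ()
    floor: float | None = None

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("log-expression matrix contains non-finite values")
        if self.floor is None:
            self.floor = float(arr.min()) if arr.size else 0.0

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape
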