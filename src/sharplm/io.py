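"""Readers and writers for the external formats the pipeline consumes.

Count matrices come in as plain TSV (gene ids in the first column, sample
ids in the header) or GCT 1.2; gene sets as GMT; sample metadata and
signature tables as TSV.  All stage outputs are tab-separated with a
single header row and floats serialized at 10 significant digits, which
makes every table round-trippable at test tolerances.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, GeneSet, GeneSetCollection, SampleTable

logger = logging.getLogger("sharplm")

FLOAT_FORMAT = "%.10g"


def read_counts(path, fmt: str | None = None) -> CountMatrix:
    """Read a genes x samples count matrix from TSV or GCT 1.2.

    ``fmt`` may be ``"tsv"`` or ``"gct"``; when None it is inferred from
    the file extension (``.gct`` => GCT).  Invariants (unique ids,
    non-negative integer counts) are enforced on load.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif fmt == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1.2"):
                raise ValueError(f"{path}: not a GCT 1.2 file (header {version!r})")
            dims = fh.readline().split()
            n_genes, n_samples = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", index_col=0)
        df = df.drop(columns=["Description"], errors="ignore")
        if df.shape != (n_genes, n_samples):
            raise ValueError(
                f"{path}: GCT dimension line says {n_genes}x{n_samples}, "
                f"found {df.shape[0]}x{df.shape[1]}"
            )
    else:
        raise ValueError(f"unknown count format {fmt!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountMatrix(df)


def write_counts(cm: CountMatrix, path) -> None:
    df = cm.counts.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_samples(path, age_range: tuple[float, float] = (18.0, 100.0)) -> SampleTable:
    """Read a sample metadata TSV indexed by its first (sample id) column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SampleTable(df, age_range)


def write_samples(st: SampleTable, path) -> None:
    df = st.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_gmt(path, source: str = "") -> GeneSetCollection:
    """Read a GMT file: ``name <TAB> description <TAB> gene1 <TAB> ...``.

    Duplicate genes within a set are dropped (first occurrence kept);
    sets left empty are dropped with a logged warning.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name, description = fields[0], fields[1]
            genes = list(dict.fromkeys(g for g in fields[2:] if g.strip()))
            if not genes:
                logger.warning("GMT %s:%d: set %r is empty, dropped", path, lineno, name)
                continue
            coll.add(GeneSet(name, tuple(genes), source=source, description=description))
    return coll


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in coll:
            fh.write("\t".join([gs.name, gs.description or gs.source, *gs.genes]) + "\n")


def read_signatures(path) -> dict[str, list[str]]:
    """Read a two-column (label, gene) TSV into label -> gene list."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: signature table needs 2 columns (label, gene)")
    label_col, gene_col = df.columns[:2]
    out: dict[str, list[str]] = {}
    for label, sub in df.groupby(label_col, sort=False):
        out[str(label)] = list(dict.fromkeys(sub[gene_col].astype(str)))
    return out


def write_signatures(signatures: dict[str, list[str]], path) -> None:
    rows = [(label, g) for label, genes in signatures.items() for g in genes]
    pd.DataFrame(rows, columns=["label", "gene"]).to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a stage output table: TSV, one header row, 10-sig-digit floats."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_expression(expr, path) -> None:
    df = expr.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_expression(path):
    from .datatypes import LogExpressionMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return LogExpressionMatrix(df)


def write_manifest(out_dir, config: dict, seed: int | None, stage: str) -> Path:
    """Write the run manifest (stage, config, seed, versions) as JSON."""
    from importlib.metadata import version

    from . import __version__

    deps = ["numpy", "scipy", "pandas", "statsmodels", "scikit-learn",
            "click", "pyyaml"]
    manifest = {
        "stage": stage,
        "seed": seed,
        "config": _jsonable(config),
        "versions": {
            "sharplm": __version__,
            "python": platform.python_version(),
            **{d: version(d) for d in deps},
        },
    }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
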