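"""Grouping of gene sets from multiple sources into pathway families.

Pairwise similarity of pathways is the overlap index

    OI(i, j) = |Gi ∩ Gj| / min(|Gi|, |Gj|)

which equals 1 when one set nests inside the other and 0 when they are
disjoint.  Pathways that are subsets of larger pathways are removed
first (and later inherit the family of their smallest parent).  Rows of
the OI matrix are correlated pairwise (Pearson), Euclidean distances are
taken between rows of that correlation matrix, and complete-linkage
agglomerative clustering cut at exactly K clusters (default 10) yields
the families.  Everything in this module is deterministic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import pdist, squareform

from .datatypes import GeneSetCollection

logger = logging.getLogger("sharplm")

__all__ = [
    "overlap_index_matrix",
    "remove_subset_pathways",
    "cluster_pathways",
    "assign_subset_pathways",
    "family_term_frequencies",
    "build_families",
    "FamilyAssignment",
    "DEFAULT_STOPWORDS",
]


def overlap_index_matrix(collection: GeneSetCollection) -> pd.DataFrame:
    """Symmetric overlap-index matrix with unit diagonal.

    OI(i, j) = |Gi ∩ Gj| / min(|Gi|, |Gj|), in [0, 1].
    """
    names = collection.names
    if len(names) < 2:
        raise ValueError("need at least 2 pathways")
    sets = [collection[n].as_set() for n in names]
    sizes = np.array([len(s) for s in sets])
    n = len(sets)
    oi = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            oi[i, j] = oi[j, i] = inter / min(sizes[i], sizes[j])
    out = pd.DataFrame(oi, index=names, columns=names)
    assert np.allclose(out.values, out.values.T) and np.allclose(np.diag(out.values), 1.0)
    return out


def remove_subset_pathways(
    collection: GeneSetCollection,
) -> tuple[GeneSetCollection, dict[str, list[str]]]:
    """Remove pathways fully contained in another pathway's gene set.

    Returns the kept collection and a parent map: removed pathway ->
    every kept strict superset.  Identical sets keep only the
    lexicographically first name; the others record the kept one as
    parent.  Idempotent.
    """
    names = sorted(collection.names)
    sets = {n: collection[n].as_set() for n in names}
    removed: dict[str, list[str]] = {}
    for name in names:
        parents = []
        for other in names:
            if other == name:
                continue
            if sets[name] < sets[other]:
                parents.append(other)
            elif sets[name] == sets[other] and other < name:
                parents.append(other)
        if parents:
            removed[name] = parents
    kept_names = [n for n in collection.names if n not in removed]
    # parents must themselves be kept (a transitively nested parent is
    # itself removed); keep only kept parents, which always exist for
    # strict subsets and for duplicate groups resolve to the kept name
    parent_map = {}
    for name, parents in removed.items():
        kept_parents = [p for p in parents if p not in removed]
        if not kept_parents:
            # all parents removed: follow duplicates to their kept parent
            kept_parents = sorted(
                {kp for p in parents for kp in removed.get(p, []) if kp not in removed}
            )
        parent_map[name] = kept_parents
    return collection.subset(kept_names), parent_map


@dataclass
class FamilyAssignment:
    """Pathway -> family id (1..K) plus per-family membership."""

    assignment: dict[str, int]
    k: int
    term_frequencies: dict[int, pd.Series] = field(default_factory=dict)

    def members(self, family: int) -> list[str]:
        return sorted(n for n, f in self.assignment.items() if f == family)

    @property
    def n_families(self) -> int:
        return len(set(self.assignment.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignment.items()), columns=["pathway", "family"]
        )


def cluster_pathways(
    oi: pd.DataFrame, k: int = 10, distance: str = "euclidean_rows"
) -> FamilyAssignment:
    """Complete-linkage clustering of OI-profile correlations into K families.

    Rows of the OI matrix are correlated pairwise (Pearson; rows of zero
    variance get correlation 0 with a warning); by default Euclidean
    distances are computed between rows of the correlation matrix
    (``distance="euclidean_rows"``), with ``"one_minus_cor"`` available
    as the alternative reading.  The complete-linkage tree is cut to
    exactly K clusters; family ids are relabelled 1..K in order of first
    appearance in the input.
    """
    n = oi.shape[0]
    if k > n:
        raise ValueError(f"K={k} exceeds the number of pathways ({n})")
    mat = oi.to_numpy(dtype=float)
    sd = mat.std(axis=1)
    if (sd == 0).any():
        logger.warning(
            "cluster_pathways: %d constant OI rows; their correlations set to 0",
            int((sd == 0).sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    if n == k:
        labels = np.arange(n)
    else:
        if distance == "euclidean_rows":
            dist = pdist(corr, metric="euclidean")
        elif distance == "one_minus_cor":
            dist = squareform(1.0 - corr, checks=False)
        else:
            raise ValueError(f"unknown distance {distance!r}")
        z = linkage(dist, method="complete")
        labels = cut_tree(z, n_clusters=k).ravel()
    # relabel deterministically by first appearance
    relabel: dict[int, int] = {}
    assignment = {}
    for name, lab in zip(oi.index, labels):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        assignment[str(name)] = relabel[lab]
    return FamilyAssignment(assignment, k=k)


def assign_subset_pathways(
    assignment: FamilyAssignment,
    parent_map: dict[str, list[str]],
    collection: GeneSetCollection,
) -> FamilyAssignment:
    """Give removed subset pathways the family of their smallest parent.

    Ties in parent size resolve to the lexicographically first parent
    name.  Every pathway of the original collection ends up assigned.
    """
    merged = dict(assignment.assignment)
    for daughter, parents in parent_map.items():
        clustered = [p for p in parents if p in merged]
        if not clustered:
            raise AssertionError(f"daughter {daughter!r} has no clustered parent")
        best = min(clustered, key=lambda p: (len(collection[p]), p))
        merged[daughter] = merged[best]
    return FamilyAssignment(merged, k=assignment.k)


DEFAULT_STOPWORDS = frozenset(
    {
        "a", "an", "and", "as", "at", "by", "for", "from", "in", "into",
        "is", "its", "of", "on", "or", "the", "to", "via", "with",
        "pathway", "signaling", "signalling", "regulation",
    }
)


def family_term_frequencies(
    assignment: FamilyAssignment,
    stopwords: frozenset[str] | set[str] = DEFAULT_STOPWORDS,
) -> dict[int, pd.Series]:
    """Token counts of member pathway names per family, sorted descending.

    Names are lowercased and tokenized on non-alphanumeric characters;
    stop words are removed.  Replaces word-cloud rendering with a table.
    """
    out: dict[int, pd.Series] = {}
    for family in sorted(set(assignment.assignment.values())):
        tokens: list[str] = []
        for name in assignment.members(family):
            tokens.extend(
                t for t in re.split(r"[^0-9a-z]+", name.lower())
                if t and t not in stopwords
            )
        counts = pd.Series(tokens, dtype=object).value_counts() if tokens else pd.Series(dtype=int)
        out[family] = counts
    assignment.term_frequencies = out
    return out


def build_families(
    collection: GeneSetCollection, k: int = 10,
    stopwords: frozenset[str] | set[str] = DEFAULT_STOPWORDS,
) -> FamilyAssignment:
    """Full pipeline: subset removal, OI clustering, subset re-assignment,
    term frequencies."""
    kept, parent_map = remove_subset_pathways(collection)
    oi = overlap_index_matrix(kept)
    assignment = cluster_pathways(oi, k=k)
    assignment = assign_subset_pathways(assignment, parent_map, collection)
    family_term_frequencies(assignment, stopwords=stopwords)
    return assignment
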