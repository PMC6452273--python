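"""Signed association matrix and hierarchical clustering of its rows/columns.

Each (cas subtype, repair component) pair is scored -1 (significant
negative association), +1 (significant positive) or 0, where "significant"
requires both the Fisher/Bonferroni screen call and the phylogenetic
median-LRT call.  Rows and columns with no nonzero entry are dropped, and
the remaining matrix is clustered with agglomerative single-linkage
(nearest-neighbour) clustering on Euclidean distance, rows and columns
independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance


@dataclass
class SignedMatrix:
    """{-1, 0, +1} association matrix: rows = cas ids, columns = system ids."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size and not np.isin(arr, (-1, 0, 1)).all():
            raise ValueError("signed matrix entries must be in {-1, 0, 1}")

    @property
    def empty(self) -> bool:
        return self.values.size == 0


@dataclass
class ClusterResult:
    """Leaf orders and merge tables from single-linkage clustering."""

    row_order: list
    col_order: list
    row_merges: pd.DataFrame  # columns: child1, child2, distance, size
    col_merges: pd.DataFrame


def signed_matrix(records) -> SignedMatrix:
    """Build the signed matrix from per-pair screen + phylogenetic results.

    ``records`` is an iterable of dicts (or a DataFrame) with keys
    ``system``, ``cas``, ``phi``, ``bonferroni_significant`` and
    ``phylo_significant``; ``phylo_significant`` may be None only for pairs
    that already failed the Bonferroni screen (the phylogenetic test is
    gated on that screen).  Rows and columns without any nonzero entry are
    dropped.
    """
    if isinstance(records, pd.DataFrame):
        records = records.to_dict("records")
    records = list(records)
    if not records:
        raise ValueError("no records supplied")
    signs = {}
    for rec in records:
        key = (rec["cas"], rec["system"])
        bonf = bool(rec["bonferroni_significant"])
        phylo = rec.get("phylo_significant")
        if bonf and phylo is None:
            raise ValueError(
                f"pair (system={rec['system']}, cas={rec['cas']}) passed the "
                "screen but has no phylogenetic test outcome"
            )
        if bonf and bool(phylo) and rec["phi"] != 0 and not np.isnan(rec["phi"]):
            signs[key] = 1 if rec["phi"] > 0 else -1
        else:
            signs[key] = 0
    cas_ids = sorted({k[0] for k in signs})
    sys_ids = sorted({k[1] for k in signs})
    mat = pd.DataFrame(0, index=cas_ids, columns=sys_ids, dtype=int)
    for (ca, s), v in signs.items():
        mat.loc[ca, s] = v
    keep_rows = mat.index[(mat != 0).any(axis=1)]
    keep_cols = mat.columns[(mat != 0).any(axis=0)]
    return SignedMatrix(mat.loc[keep_rows, keep_cols])


def _single_linkage(data: np.ndarray) -> pd.DataFrame:
    """Single-linkage merge table for the rows of ``data`` (Euclidean)."""
    n = data.shape[0]
    cols = ["child1", "child2", "distance", "size"]
    if n < 2:
        return pd.DataFrame(columns=cols)
    condensed = scipy.spatial.distance.pdist(data, metric="euclidean")
    Z = scipy.cluster.hierarchy.linkage(condensed, method="single")
    df = pd.DataFrame(Z, columns=cols)
    df[["child1", "child2", "size"]] = df[["child1", "child2", "size"]].astype(int)
    return df


def _leaf_order(merges: pd.DataFrame, n: int) -> list[int]:
    if n == 1:
        return [0]
    Z = merges[["child1", "child2", "distance", "size"]].to_numpy(dtype=float)
    return list(scipy.cluster.hierarchy.leaves_list(Z))


def cluster(mat: SignedMatrix) -> ClusterResult:
    """Single-linkage clustering of rows and columns of the signed matrix.

    Returns leaf orders (as row/column labels) and the two merge tables in
    scipy linkage convention (children >= n denote previously formed
    clusters).
    """
    if mat.empty:
        raise ValueError("cannot cluster an empty signed matrix")
    data = mat.values.to_numpy(dtype=float)
    row_merges = _single_linkage(data)
    col_merges = _single_linkage(data.T)
    row_order = [
        mat.values.index[i] for i in _leaf_order(row_merges, data.shape[0])
    ]
    col_order = [
        mat.values.columns[i] for i in _leaf_order(col_merges, data.shape[1])
    ]
    return ClusterResult(row_order, col_order, row_merges, col_merges)
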