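"""Multivariate summaries and plot-ready exports.

The core stays numeric: PCA of the significant-fragment matrix with
explained-variance fractions, a hierarchically clustered heatmap matrix
export with row feature metadata, and a Sankey-ready link table joining
genes to their feature location, supplied functional category and
response class.  Any plotting layer can consume the TSVs; no figures are
rendered here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.decomposition import PCA

from .detection import MethMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PCAResult:
    """Sample coordinates and explained-variance fractions.

    ``coordinates``: DataFrame indexed by (participant, timepoint) with
    PC1..PCk columns.  Fractions are non-increasing and sum to 1 when all
    min(samples-1, fragments) components are retained.
    """

    coordinates: pd.DataFrame
    explained_variance_fraction: np.ndarray

    def combined_variance(self, n: int = 2) -> float:
        """Summed explained fraction of the first ``n`` components."""
        return float(self.explained_variance_fraction[:n].sum())


def pca_timepoints(
    matrix: MethMatrix,
    n_components: int | None = None,
    scale: bool = False,
) -> PCAResult:
    """PCA with samples as observations and fragments as variables.

    Columns are centred; unit-variance scaling is off by default since
    methylation fractions share a scale.  Sign convention: within each
    component the largest-magnitude loading is made positive.
    """
    values = matrix.values
    if values.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    if values.isna().any().any():
        raise ValueError("PCA requires complete cases")
    X = values.to_numpy(dtype=float).T  # samples x fragments
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    k = min(X.shape[0] - 1, X.shape[1]) if n_components is None else n_components
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    # deterministic sign: largest-|loading| positive per component
    for j in range(pca.components_.shape[0]):
        i = int(np.argmax(np.abs(pca.components_[j])))
        if pca.components_[j, i] < 0:
            pca.components_[j] *= -1
            coords[:, j] *= -1
    frame = pd.DataFrame(
        coords,
        index=values.columns,
        columns=[f"PC{j + 1}" for j in range(coords.shape[1])],
    )
    return PCAResult(frame, pca.explained_variance_ratio_.copy())


def _average_linkage_order(X: np.ndarray) -> list[int]:
    """Leaf order from average-linkage agglomeration on Euclidean distances.

    Deterministic tie-breaks: merge the pair at minimal distance, ties
    resolved by the smallest (leftmost-leaf, leftmost-leaf) index pair;
    the child whose leftmost input row comes first becomes the left
    subtree, and leaves are read left-subtree-first — so an all-equal
    matrix preserves input order.
    """
    n = X.shape[0]
    if n <= 1:
        return list(range(n))
    D = squareform(pdist(X, metric="euclidean"))
    # cluster id -> (size, leaves-in-order); leftmost leaf keys the ties
    active: dict[int, tuple[int, list[int]]] = {i: (1, [i]) for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): D[i, j] for i in range(n) for j in range(i + 1, n)
    }
    left = {i: i for i in range(n)}
    next_id = n
    while len(active) > 1:
        (i, j) = min(
            dist,
            key=lambda k: (
                dist[k],
                min(left[k[0]], left[k[1]]),
                max(left[k[0]], left[k[1]]),
            ),
        )
        ni, leaves_i = active.pop(i)
        nj, leaves_j = active.pop(j)
        if left[i] <= left[j]:
            merged = (ni + nj, leaves_i + leaves_j)
        else:
            merged = (ni + nj, leaves_j + leaves_i)
        del dist[(i, j)]
        new_dists = {}
        for k in active:
            a = dist.pop((min(i, k), max(i, k)))
            b = dist.pop((min(j, k), max(j, k)))
            new_dists[(min(k, next_id), max(k, next_id))] = (ni * a + nj * b) / (ni + nj)
        active[next_id] = merged
        left[next_id] = min(left[i], left[j])
        dist.update(new_dists)
        next_id += 1
    return next(iter(active.values()))[1]


def heatmap_export(
    values: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster rows (Euclidean, average linkage) and order columns
    timepoint-major; returns (ordered matrix, row metadata).

    ``values``: fragments x (participant, timepoint) in [0, 1], complete.
    ``annotations``: optional per-fragment metadata (e.g. feature class)
    indexed like ``values``; reindexed to the clustered row order.
    """
    if values.isna().any().any():
        raise ValueError("heatmap export requires complete cases")
    arr = values.to_numpy(dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError("heatmap values must lie in [0, 1]")
    order = _average_linkage_order(arr)
    ordered = values.iloc[order]
    if isinstance(ordered.columns, pd.MultiIndex):
        col_order = sorted(
            range(len(ordered.columns)),
            key=lambda i: (ordered.columns[i][1], ordered.columns[i][0]),
        )
        ordered = ordered.iloc[:, col_order]
    if annotations is None:
        meta = pd.DataFrame(index=ordered.index)
    else:
        meta = annotations.reindex(ordered.index)
    return ordered, meta


def write_heatmap_tsv(ordered: pd.DataFrame, path) -> None:
    ordered.to_csv(path, sep="\t")


def read_heatmap_tsv(path) -> pd.DataFrame:
    """Read a heatmap TSV back bit-exactly (round-trip float parsing)."""
    return pd.read_csv(
        path, sep="\t", header=[0, 1], index_col=0, float_precision="round_trip"
    )


def build_link_table(
    annotated_dmfs: pd.DataFrame,
    category_map: Mapping[str, str],
) -> pd.DataFrame:
    """One (gene_id, feature_location, functional_category, response_class)
    row per gene-linked DMF; genes missing from the supplied map get the
    category "Unknown" with a warning.  Categories are an input mapping,
    never computed here."""
    required = {"gene_id", "feature", "assigned_category"}
    missing = required - set(annotated_dmfs.columns)
    if missing:
        raise ValueError(f"annotated DMF table lacks columns {sorted(missing)}")
    linked = annotated_dmfs.dropna(subset=["gene_id"])
    unmapped = sorted(set(linked["gene_id"]) - set(category_map))
    if unmapped:
        logger.warning(
            "no functional category for %d genes (e.g. %s); using 'Unknown'",
            len(unmapped),
            unmapped[:5],
        )
    return pd.DataFrame(
        {
            "gene_id": linked["gene_id"].to_numpy(),
            "feature_location": linked["feature"].to_numpy(),
            "functional_category": [
                category_map.get(g, "Unknown") for g in linked["gene_id"]
            ],
            "response_class": linked["assigned_category"].to_numpy(),
        }
    )


def genes_by_response(link_table: pd.DataFrame) -> dict[str, list[str]]:
    """Unique gene lists per response class (early/late/gradual)."""
    out: dict[str, list[str]] = {}
    for cls, sub in link_table.groupby("response_class"):
        out[str(cls)] = sorted(set(sub["gene_id"]))
    return out


def read_category_map(path) -> dict[str, str]:
    """Two-column TSV gene_id -> functional_category."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns[:2])
    return dict(zip(df[cols[0]].astype(str), df[cols[1]].astype(str)))
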