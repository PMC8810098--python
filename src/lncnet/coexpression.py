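"""lncRNA-mRNA Pearson co-expression: edges, top correlates, cluster order.

Edges connect each differentially expressed lncRNA (DEL) to every mRNA
probe; an edge passes when |r| >= corr_r_threshold (inclusive) and its
significance -- raw p or BH q within the lncRNA's edge family, depending
on ``corr_adjust`` -- is <= corr_p_threshold (inclusive).  Correlations
pool both sample groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .config import AnalysisConfig
from .data_model import MRNA, ExpressionMatrix
from .differential import bh_adjust
from .errors import DegenerateInputError

log = logging.getLogger(__name__)

EDGE_COLUMNS = ["lncrna_id", "mrna_id", "r", "p_value", "q_value", "n", "passes"]


def pearson_with_p(x: Iterable[float], y: Iterable[float]) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-distribution p-value.

    p derives from t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 df; perfectly
    collinear input returns p = 0.  Constant input is degenerate.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("pearson_with_p requires n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("input contains non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant vector has no defined correlation")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    n = x.size
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(min(p, 1.0))


def _correlation_block(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between every row of ``a`` and every row of ``b`` (same width)."""
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    az /= np.linalg.norm(az, axis=1, keepdims=True)
    bz /= np.linalg.norm(bz, axis=1, keepdims=True)
    return np.clip(az @ bz.T, -1.0, 1.0)


def _p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore"):
        t = np.abs(r) * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(t, n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, np.clip(p, 0.0, 1.0))


def build_edges(dels: Sequence[str], matrix: ExpressionMatrix,
                annot: pd.DataFrame, config: AnalysisConfig | None = None,
                ) -> pd.DataFrame:
    """All lncRNA-mRNA correlation edges for the given DEL probe ids.

    Returns one row per (DEL, non-degenerate mRNA probe) with r, p, the
    BH q within that DEL's edge family, and the ``passes`` flag evaluated
    under ``config.corr_adjust``.  Constant (zero-variance) probes on
    either side are skipped with a logged count.
    """
    config = config or AnalysisConfig()
    dels = list(dels)
    mrna_ids = [p for p in matrix.probe_ids
                if p in annot.index and annot.at[p, "biotype"] == MRNA]
    values = matrix.values
    n = values.shape[1]

    skipped = 0
    lnc_keep, mrna_keep = [], []
    for pid in dels:
        if np.ptp(values.loc[pid].to_numpy()) == 0:
            skipped += 1
        else:
            lnc_keep.append(pid)
    mrna_values = values.loc[mrna_ids].to_numpy(dtype=float)
    nondeg = np.ptp(mrna_values, axis=1) != 0
    skipped += int((~nondeg).sum())
    mrna_keep = [p for p, ok in zip(mrna_ids, nondeg) if ok]
    if skipped:
        log.warning("build_edges: skipped %d constant probe(s)", skipped)
    if not lnc_keep or not mrna_keep:
        return pd.DataFrame(columns=EDGE_COLUMNS)

    r = _correlation_block(values.loc[lnc_keep].to_numpy(dtype=float),
                           values.loc[mrna_keep].to_numpy(dtype=float))
    p = _p_from_r(r, n)
    q = np.vstack([bh_adjust(row) for row in p])

    sig = q if config.corr_adjust == "bh" else p
    passes = (np.abs(r) >= config.corr_r_threshold) & \
        (sig <= config.corr_p_threshold)

    n_m = len(mrna_keep)
    return pd.DataFrame({
        "lncrna_id": np.repeat(lnc_keep, n_m),
        "mrna_id": np.tile(mrna_keep, len(lnc_keep)),
        "r": r.ravel(),
        "p_value": p.ravel(),
        "q_value": q.ravel(),
        "n": n,
        "passes": passes.ravel(),
    })


def top_correlates(edges: pd.DataFrame, lncrna_id: str, k: int = 30) -> list[str]:
    """The k mRNAs most correlated with one lncRNA.

    Passing edges are preferred; within each stratum the order is
    descending |r| with ties broken by mRNA id.  Fewer than k edges
    returns them all.
    """
    fam = edges[edges["lncrna_id"] == lncrna_id]
    if fam.empty:
        raise KeyError(f"no edges for lncRNA {lncrna_id!r}")
    order = fam.assign(abs_r=fam["r"].abs()).sort_values(
        ["passes", "abs_r", "mrna_id"], ascending=[False, False, True],
        kind="mergesort")
    return order["mrna_id"].head(k).tolist()


@dataclass
class ClusterOrder:
    """Deterministic leaf order + linkage trace from average-linkage clustering."""

    item_ids: list[str]
    linkage: np.ndarray  # scipy (n-1, 4) merge trace


def _deterministic_leaves(Z: np.ndarray, n: int) -> list[int]:
    """Leaf order placing, at every merge, the subtree holding the
    smallest original index first."""
    def walk(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        la, lb = walk(a), walk(b)
        return la + lb if min(la) < min(lb) else lb + la
    return walk(2 * n - 2) if n > 1 else [0]


def cluster_order(values: pd.DataFrame) -> ClusterOrder:
    """Average-linkage agglomerative clustering under 1 - Pearson r distance.

    ``values`` holds one row per item (probes or samples).  Constant rows
    have no defined correlation and are assigned the maximal distance 2.0
    to every other item, with a warning.  Rows and columns of a heatmap
    can be ordered independently by clustering the matrix and its
    transpose.
    """
    if len(values) < 2:
        raise ValueError("cluster_order requires >= 2 items")
    arr = values.to_numpy(dtype=float)
    constant = np.ptp(arr, axis=1) == 0
    if constant.any():
        log.warning("cluster_order: %d constant profile(s) assigned maximal "
                    "distance", int(constant.sum()))
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(arr)
    dist = 1.0 - corr
    dist[np.isnan(dist)] = 2.0
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    np.clip(dist, 0.0, 2.0, out=dist)
    Z = linkage(squareform(dist, checks=False), method="average")
    order = _deterministic_leaves(Z, len(values))
    return ClusterOrder([values.index[i] for i in order], Z)
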