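"""Developmental-time propagation by k-NN median voting.

Cells that carry a barcode-derived timestamp anchor the time axis; each
remaining cell receives the median timestamp of its k nearest timestamped
neighbors in expression space (default 20), but only when the neighbors'
timestamps agree — their standard deviation must fall below a gate
(default 1 h).  Barcode-derived times are never overwritten.  Leave-one-out
validation re-predicts each timestamped cell from its neighbors (excluding
itself) to estimate the transfer accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from ._utils import knn_indices

__all__ = [
    "TimeTable",
    "NeighborGraph",
    "build_neighbor_graph",
    "propagate_times",
    "loo_validate",
    "concordance",
    "pca_embedding",
]


@dataclass
class NeighborGraph:
    """Per-cell neighbor indices (into a reference set) with distances."""

    indices: np.ndarray          # (n_query, k) into reference rows
    distances: np.ndarray        # (n_query, k)
    k: int
    query_ids: list[str]
    reference_ids: list[str]
    n_components: int


def build_neighbor_graph(
    embedding: np.ndarray,
    k: int = 20,
    metric: str = "euclidean",
    query_ids: list[str] | None = None,
    reference_mask: np.ndarray | None = None,
    exclude_self: bool = False,
) -> NeighborGraph:
    """Exact k-NN over an embedding, deterministic under the tie rule.

    Neighbors are drawn from rows where ``reference_mask`` is True (all
    rows by default).  ``exclude_self`` drops each query row from its own
    neighbor list (requires queries to be rows of the embedding).  Distance
    ties break by ascending row index.
    """
    emb = np.asarray(embedding, dtype=float)
    n = emb.shape[0]
    ids = query_ids if query_ids is not None else [str(i) for i in range(n)]
    if reference_mask is None:
        reference_mask = np.ones(n, dtype=bool)
    ref_rows = np.flatnonzero(reference_mask)
    n_ref = ref_rows.size
    avail = n_ref - 1 if exclude_self else n_ref
    if k >= n and reference_mask.all() and exclude_self:
        raise ValueError(f"k={k} too large for {n} cells")
    if k > avail:
        raise ValueError(f"k={k} exceeds available reference cells ({avail})")
    exclude = None
    if exclude_self:
        pos_in_ref = np.full(n, -1, dtype=int)
        pos_in_ref[ref_rows] = np.arange(n_ref)
        exclude = pos_in_ref
    idx_local, dists = knn_indices(emb, emb[ref_rows], k, exclude_identity=exclude,
                                   metric=metric)
    return NeighborGraph(
        indices=ref_rows[idx_local],
        distances=dists,
        k=k,
        query_ids=list(ids),
        reference_ids=[ids[i] for i in ref_rows],
        n_components=emb.shape[1] if emb.ndim == 2 else 1,
    )


def pca_embedding(X: np.ndarray, n_components: int = 35, seed: int = 0) -> np.ndarray:
    """PCA of a (log-normalized) expression matrix for neighbor graphs.

    35 components by default, matching the dimensionality used for
    denoising and label transfer throughout the pipeline.
    """
    from sklearn.decomposition import PCA

    X = np.asarray(X, dtype=float)
    n_comp = min(n_components, min(X.shape) - 1)
    return PCA(n_components=n_comp, svd_solver="full", random_state=seed).fit_transform(X)


def _neighbor_vote(times_ref: np.ndarray, neigh: np.ndarray, sd_max: float,
                   population_sd: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    vals = times_ref[neigh]                      # (n, k)
    med = np.median(vals, axis=1)
    ddof = 0 if population_sd else 1
    sd = np.std(vals, axis=1, ddof=ddof)
    ok = sd < sd_max
    return med, sd, ok


def propagate_times(
    times: pd.DataFrame,
    embedding: np.ndarray,
    k: int = 20,
    sd_max: float = 1.0,
    population_sd: bool = True,
) -> pd.DataFrame:
    """Impute times for cells lacking a barcode-derived timestamp.

    ``times`` is indexed by cell with a ``barcode_time_hpf`` column (NaN
    where missing); rows align with ``embedding``.  Neighbors are drawn
    among timestamped cells only (the median is undefined otherwise).  A
    cell is assigned iff the neighbor SD is strictly below ``sd_max``
    (population formula, divisor n, by default).  The output adds
    inferred_time_hpf, final_time_hpf and status in {barcode, inferred,
    unassigned}; barcode-derived times are always retained as final.
    """
    if sd_max <= 0:
        raise ValueError("sd_max must be positive")
    out = times.copy()
    bt = out["barcode_time_hpf"].to_numpy(float)
    has_bt = np.isfinite(bt)
    n_ts = int(has_bt.sum())
    out["inferred_time_hpf"] = np.nan
    out["status"] = np.where(has_bt, "barcode", "unassigned")
    query = ~has_bt
    if query.any() and n_ts >= 1:
        kk = min(k, n_ts)
        emb = np.asarray(embedding, dtype=float)
        idx_local, _ = knn_indices(emb[query], emb[has_bt], kk)
        med, sd, ok = _neighbor_vote(bt[has_bt], idx_local, sd_max, population_sd)
        inferred = np.where(ok, med, np.nan)
        col = out.columns.get_loc("inferred_time_hpf")
        out.iloc[np.flatnonzero(query), col] = inferred
        st = out["status"].to_numpy(object)
        st[np.flatnonzero(query)[ok]] = "inferred"
        out["status"] = st
    out["final_time_hpf"] = np.where(has_bt, bt, out["inferred_time_hpf"].to_numpy(float))
    return out


def loo_validate(
    times: pd.DataFrame,
    embedding: np.ndarray,
    k: int = 20,
    sd_max: float = 1.0,
    exact_tol: float = 0.5,
    within_tol: float = 1.0,
    population_sd: bool = True,
) -> dict:
    """Leave-one-out validation of the time-transfer rule.

    Each timestamped cell is re-predicted from its k nearest timestamped
    neighbors excluding itself.  ``frac_exact`` is the fraction of
    *predicted* cells whose |inferred - true| <= ``exact_tol`` (the median
    of an even neighbor count can fall on half hours, hence a 0.5 h
    equality tolerance); ``frac_within_tol`` likewise at ``within_tol``;
    ``frac_unassigned`` is the SD-gate rejection rate over all timestamped
    cells.
    """
    bt = times["barcode_time_hpf"].to_numpy(float)
    has_bt = np.isfinite(bt)
    n_ts = int(has_bt.sum())
    if n_ts < 2:
        raise ValueError("need at least 2 timestamped cells")
    kk = min(k, n_ts - 1)
    emb = np.asarray(embedding, dtype=float)
    ts_rows = np.flatnonzero(has_bt)
    idx_local, _ = knn_indices(emb[ts_rows], emb[ts_rows], kk,
                               exclude_identity=np.arange(n_ts))
    med, sd, ok = _neighbor_vote(bt[ts_rows], idx_local, sd_max, population_sd)
    err = np.abs(med - bt[ts_rows])
    n_pred = int(ok.sum())
    return {
        "n_timestamped": n_ts,
        "n_predicted": n_pred,
        "frac_exact": float(np.mean(err[ok] <= exact_tol)) if n_pred else float("nan"),
        "frac_within_tol": float(np.mean(err[ok] <= within_tol)) if n_pred else float("nan"),
        "frac_unassigned": float(1 - n_pred / n_ts),
    }


def concordance(final_times: pd.Series | np.ndarray, pseudotime: pd.Series | np.ndarray) -> float:
    """Spearman rank correlation between (inferred) real time and pseudotime."""
    t = np.asarray(final_times, dtype=float)
    p = np.asarray(pseudotime, dtype=float)
    ok = np.isfinite(t) & np.isfinite(p)
    if ok.sum() < 3:
        raise ValueError("need at least 3 cells with both values")
    if np.all(t[ok] == t[ok][0]) or np.all(p[ok] == p[ok][0]):
        raise ValueError("constant input: rank correlation undefined")
    return float(spearmanr(t[ok], p[ok]).statistic)


@dataclass
class TimeTable:
    """Convenience wrapper building the per-cell time table."""

    table: pd.DataFrame

    @classmethod
    def from_assignment(cls, assignment: pd.DataFrame) -> "TimeTable":
        """From a demux assignment carrying time_hpf for assigned cells."""
        df = pd.DataFrame(index=assignment.index)
        df["barcode_time_hpf"] = assignment.get("time_hpf", np.nan)
        df.loc[assignment["status"] != "assigned", "barcode_time_hpf"] = np.nan
        return cls(df)
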