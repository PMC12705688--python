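"""Trajectory maturation: smoothing, pseudotime, states, gene programs.

Cells ordered along a developmental trajectory transition through a small
number of regulatory states; gene programs (clusters of genes with shared
temporal profiles) rise and fall along the way.  Programs peaking shortly
before the lineage bifurcation, after an initially silent phase, are
*mature*; the earliest program active in the founder population is
*immature*; branch-restricted post-bifurcation programs are *terminal*.
The module provides a one-step graph smoother (neighbor averaging over a
k=18 graph on 35 PCs by default), diffusion pseudotime rooted at a
minimum-time cell, Ward segmentation into regulatory states, Leiden
clustering of the transposed gene matrix, maturity labeling, Wilcoxon
marker calling, and a velocity-speed proxy (the norm of per-gene expression
slopes along pseudotime).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from ._utils import knn_indices
from .stats import adjust_pvalues

__all__ = [
    "GeneClusterTable",
    "normalize_log1p_cp10k",
    "smooth_expression",
    "compute_pseudotime",
    "segment_states",
    "cluster_genes",
    "cluster_profiles",
    "label_maturity",
    "find_markers",
    "velocity_speed",
    "intersect_maturity_sets",
]


def normalize_log1p_cp10k(counts: np.ndarray) -> np.ndarray:
    """log1p of counts-per-10k per cell (the pipeline's normalized layer)."""
    X = np.asarray(counts, dtype=float)
    total = X.sum(axis=1, keepdims=True)
    total[total == 0] = 1.0
    return np.log1p(X / total * 1e4)


def smooth_expression(
    normalized: np.ndarray,
    neighbor_indices: np.ndarray,
) -> np.ndarray:
    """One-step neighbor-mean smoother (denoising stand-in).

    Each cell's smoothed profile is the unweighted mean of itself and its
    k neighbors from a graph built on the normalized layer's PCA.  A
    single averaging pass is a deliberately simple smoother: downstream
    segmentation needs variance reduction, not a particular optimizer.
    """
    X = np.asarray(normalized, dtype=float)
    neigh = np.asarray(neighbor_indices)
    if neigh.ndim != 2 or neigh.shape[0] != X.shape[0]:
        raise ValueError("neighbor_indices must be (n_cells, k)")
    stacked = np.concatenate([np.arange(X.shape[0])[:, None], neigh], axis=1)
    return X[stacked].mean(axis=1)


def compute_pseudotime(
    normalized: np.ndarray,
    final_times: np.ndarray,
    n_pcs: int = 35,
    k: int = 18,
    seed: int = 0,
) -> np.ndarray:
    """Diffusion pseudotime rooted at a minimum-time cell, scaled to [0, 1].

    The root is drawn uniformly (seeded) among cells carrying the lowest
    final time.  Cells in graph components unreachable from the root get
    NaN.  Deterministic given the seed.
    """
    import scanpy as sc

    X = np.asarray(normalized, dtype=float)
    t = np.asarray(final_times, dtype=float)
    finite = np.isfinite(t)
    if not finite.any():
        raise ValueError("no cell carries a final time; cannot choose a root")
    rng = np.random.default_rng(seed)
    tmin = np.nanmin(t)
    candidates = np.flatnonzero(finite & (t == tmin))
    root = int(rng.choice(candidates))

    adata = ad.AnnData(X=X)
    n_comp = min(n_pcs, min(X.shape) - 1)
    sc.pp.pca(adata, n_comps=n_comp, svd_solver="arpack", random_state=0)
    sc.pp.neighbors(adata, n_neighbors=k, use_rep="X_pca", random_state=0)
    sc.tl.diffmap(adata)
    adata.uns["iroot"] = root
    sc.tl.dpt(adata)
    pt = adata.obs["dpt_pseudotime"].to_numpy(float)
    pt[~np.isfinite(pt)] = np.nan
    finite_pt = np.isfinite(pt)
    lo, hi = np.nanmin(pt), np.nanmax(pt)
    if hi > lo:
        pt[finite_pt] = (pt[finite_pt] - lo) / (hi - lo)
    else:
        pt[finite_pt] = 0.0
    return pt


def segment_states(
    smoothed: np.ndarray,
    pseudotime: np.ndarray,
    n_states: int = 5,
) -> np.ndarray:
    """Segment the trajectory into regulatory states.

    Ward agglomerative clustering of the smoothed layer into ``n_states``
    groups, renumbered 0..n-1 by increasing median pseudotime so state
    labels read as trajectory stages.
    """
    from sklearn.cluster import AgglomerativeClustering

    X = np.asarray(smoothed, dtype=float)
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if n_states > X.shape[0]:
        raise ValueError("n_states exceeds the number of cells")
    if n_states == 1:
        return np.zeros(X.shape[0], dtype=int)
    raw = AgglomerativeClustering(n_clusters=n_states, linkage="ward").fit_predict(X)
    pt = np.asarray(pseudotime, dtype=float)
    medians = {s: np.nanmedian(pt[raw == s]) for s in np.unique(raw)}
    order = sorted(medians, key=lambda s: (medians[s], s))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[s] for s in raw], dtype=int)


def cluster_genes(
    counts: np.ndarray,
    gene_ids: list[str],
    min_cells: int = 3,
    resolution: float = 1.0,
    n_pcs: int = 30,
    k: int = 15,
    seed: int = 0,
) -> pd.Series:
    """Leiden clustering of genes on the transposed expression matrix.

    Genes expressed (count > 0) in fewer than ``min_cells`` cells are
    removed; surviving genes are z-scored across cells, embedded by PCA,
    and partitioned by Leiden on a k-NN graph — the cell-clustering recipe
    applied to the transposed matrix.  Returns gene -> cluster id (int),
    deterministic given the seed.
    """
    import scanpy as sc

    X = np.asarray(counts, dtype=float)
    expressed_in = (X > 0).sum(axis=0)
    keep = expressed_in >= min_cells
    if keep.sum() < 2:
        raise ValueError("fewer than 2 genes survive the min_cells filter")
    Xg = X[:, keep].T  # genes x cells
    mu = Xg.mean(axis=1, keepdims=True)
    sd = Xg.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (Xg - mu) / sd
    gdata = ad.AnnData(X=Z)
    gdata.obs_names = [g for g, m in zip(gene_ids, keep) if m]
    n_comp = min(n_pcs, min(Z.shape) - 1)
    sc.pp.pca(gdata, n_comps=n_comp, svd_solver="arpack", random_state=0)
    sc.pp.neighbors(gdata, n_neighbors=min(k, Z.shape[0] - 1), use_rep="X_pca",
                    random_state=0)
    sc.tl.leiden(gdata, resolution=resolution, random_state=seed,
                 flavor="igraph", n_iterations=2, directed=False)
    return gdata.obs["leiden"].astype(int).rename("cluster")


@dataclass
class GeneClusterTable:
    """Gene cluster assignments with temporal profiles and maturity labels."""

    assignments: pd.Series                 # gene -> cluster id
    profiles: pd.DataFrame                 # cluster x time bin, scaled mean
    peak_time_hpf: pd.Series               # cluster -> profile argmax bin
    maturity: pd.Series | None = None      # cluster -> label
    branch_profiles: pd.DataFrame | None = None  # cluster x lineage (post-bif mean)
    meta: dict = field(default_factory=dict)

    def genes_with_maturity(self, label: str) -> set[str]:
        if self.maturity is None:
            raise ValueError("maturity labels not computed")
        clusters = set(self.maturity[self.maturity == label].index)
        return set(self.assignments[self.assignments.isin(clusters)].index)


def cluster_profiles(
    normalized: np.ndarray,
    gene_ids: list[str],
    assignments: pd.Series,
    final_times: np.ndarray,
    lineages: np.ndarray | None = None,
    bifurcation_time: float | None = None,
    bin_width_h: float = 1.0,
) -> GeneClusterTable:
    """Per-cluster scaled temporal profiles on 1-h time bins.

    Each retained gene's per-bin mean expression is z-scored across bins,
    then averaged within its cluster; the cluster peak is the bin with the
    maximal scaled mean.  When lineage labels and a bifurcation time are
    given, post-bifurcation per-branch means (on the same gene z-scores)
    are recorded for terminal-program detection.
    """
    X = np.asarray(normalized, dtype=float)
    t = np.asarray(final_times, dtype=float)
    ok = np.isfinite(t)
    if not ok.any():
        raise ValueError("no cells with final time; no time bins")
    bins = np.floor(t[ok] / bin_width_h) * bin_width_h
    uniq = np.unique(bins)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    cols = [gene_pos[g] for g in assignments.index]
    sub = X[np.ix_(ok, cols)]  # cells x retained genes

    binned = np.vstack([sub[bins == b].mean(axis=0) for b in uniq])  # bins x genes
    mu = binned.mean(axis=0, keepdims=True)
    sd = binned.std(axis=0, keepdims=True)
    flat = sd[0] == 0
    sd[:, flat] = 1.0
    Zb = (binned - mu) / sd       # bins x genes, z-scored per gene
    Zb[:, flat] = 0.0

    clusters = sorted(assignments.unique())
    prof = pd.DataFrame(
        {c: Zb[:, (assignments.to_numpy() == c)].mean(axis=1) for c in clusters},
        index=uniq,
    ).T
    prof.index.name = "cluster"
    peak = prof.idxmax(axis=1).astype(float).rename("peak_time_hpf")

    branch_prof = None
    if lineages is not None and bifurcation_time is not None:
        lin = np.asarray(lineages)[ok]
        # strictly after the split: the bifurcation bin still mixes
        # residual pre-split expression into both branches
        post = bins > bifurcation_time
        branches = sorted(x for x in np.unique(lin[post]) if x != "founder") if post.any() else []
        if branches:
            # per-gene z across cells (same scaling basis as profiles is per-bin;
            # branch contrast uses cell-level z to compare branch activity)
            cmu = sub.mean(axis=0, keepdims=True)
            csd = sub.std(axis=0, keepdims=True)
            csd[csd == 0] = 1.0
            Zc = (sub - cmu) / csd
            rows = {}
            for c in clusters:
                gm = assignments.to_numpy() == c
                rows[c] = {
                    br: float(Zc[np.ix_(post & (lin == br), gm)].mean())
                    for br in branches
                }
            branch_prof = pd.DataFrame(rows).T
            branch_prof.index.name = "cluster"
    return GeneClusterTable(assignments=assignments, profiles=prof,
                            peak_time_hpf=peak, branch_profiles=branch_prof)


def label_maturity(
    clusters: GeneClusterTable,
    bifurcation_time: float,
    window: float = 1.5,
    early_bins: int = 2,
    upregulated_threshold: float = 0.0,
    flat_range: float = 0.5,
) -> GeneClusterTable:
    """Label gene clusters immature / intermediate / mature / terminal.

    mature: scaled profile peaks within [bifurcation - window, bifurcation]
    and the early mean (first ``early_bins`` bins) sits below the
    upregulation threshold — the program switches on shortly before the
    split.  immature: the earliest-peaking cluster already upregulated in
    the founder (early) population.  terminal: peak after the bifurcation,
    or — when branch profiles exist — activity restricted to one branch
    for any late-peaking cluster (branch-restricted programs are terminal
    by definition even when time binning pins their apparent peak at the
    bifurcation bin, so the branch test precedes the mature test).  Flat
    clusters (scaled range < ``flat_range``) stay unlabeled; the rest are
    intermediate.
    """
    prof = clusters.profiles
    if prof.shape[1] == 0:
        raise ValueError("no time bins in profiles")
    bins = prof.columns.to_numpy(float)
    if not (bins.min() <= bifurcation_time <= bins.max() + 1):
        raise ValueError("bifurcation_time outside the observed time range")
    labels = {}
    early = prof.iloc[:, :early_bins].mean(axis=1)
    rng_ = prof.max(axis=1) - prof.min(axis=1)
    founder_active = early > upregulated_threshold
    candidates = clusters.peak_time_hpf[founder_active & (rng_ >= flat_range)]
    immature_cluster = candidates.idxmin() if len(candidates) else None
    def branch_restricted(c) -> bool | None:
        if clusters.branch_profiles is None or clusters.branch_profiles.shape[1] < 2:
            return None
        vals = clusters.branch_profiles.loc[c].sort_values(ascending=False)
        return bool(vals.iloc[0] > upregulated_threshold
                    and vals.iloc[1] <= upregulated_threshold)

    for c in prof.index:
        pk = clusters.peak_time_hpf[c]
        late = pk >= bifurcation_time - window
        restricted = branch_restricted(c)
        if rng_[c] < flat_range:
            labels[c] = "unlabeled"
        elif c == immature_cluster:
            labels[c] = "immature"
        elif late and restricted:
            labels[c] = "terminal"
        elif (bifurcation_time - window) <= pk <= bifurcation_time and \
                early[c] < upregulated_threshold:
            labels[c] = "mature"
        elif pk > bifurcation_time:
            labels[c] = "terminal" if restricted is None else "intermediate"
        else:
            labels[c] = "intermediate"
    clusters.maturity = pd.Series(labels).rename("maturity")
    clusters.meta.update({"bifurcation_time": bifurcation_time, "window": window})
    return clusters


def find_markers(
    normalized: np.ndarray,
    gene_ids: list[str],
    groups: np.ndarray,
    min_log2fc: float = 0.25,
    max_padj: float = 0.1,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum markers per group.

    P-values are BH-adjusted across genes within each group; reported
    markers satisfy avg log2FC >= ``min_log2fc`` (fold change of expm1
    group means, pseudocount 1e-9) and adjusted p < ``max_padj``.
    """
    X = np.asarray(normalized, dtype=float)
    g = np.asarray(groups)
    uniq = [u for u in pd.unique(g)]
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    expr = np.expm1(X)
    out = []
    for grp in uniq:
        sel = g == grp
        if sel.sum() < 2 or (~sel).sum() < 2:
            raise ValueError(f"group {grp!r} needs >= 2 cells in and out")
        pvals = mannwhitneyu(X[sel], X[~sel], alternative="two-sided", axis=0).pvalue
        pvals = np.where(np.isfinite(pvals), pvals, 1.0)
        padj = adjust_pvalues(pvals, "bh")
        lfc = np.log2((expr[sel].mean(axis=0) + 1e-9) / (expr[~sel].mean(axis=0) + 1e-9))
        keep = (lfc >= min_log2fc) & (padj < max_padj)
        for j in np.flatnonzero(keep):
            out.append({"gene": gene_ids[j], "group": grp,
                        "avg_log2fc": float(lfc[j]),
                        "p": float(pvals[j]), "p_adj": float(padj[j])})
    return pd.DataFrame(out, columns=["gene", "group", "avg_log2fc", "p", "p_adj"])


def velocity_speed(
    smoothed: np.ndarray,
    pseudotime: np.ndarray,
    half_window: int = 5,
) -> np.ndarray:
    """Speed of expression change along pseudotime.

    Cells are ordered by pseudotime (ties by index); each gene's slope at
    a cell is the finite difference across a window of ``half_window``
    rank-neighbors on each side (one-sided at the boundaries).  The speed
    is the Euclidean norm of the per-gene slope vector, a proxy for the
    velocity-vector length along the trajectory.
    """
    X = np.asarray(smoothed, dtype=float)
    pt = np.asarray(pseudotime, dtype=float)
    n = X.shape[0]
    if np.all(pt == pt[0]):
        raise ValueError("constant pseudotime")
    if n < 2 * half_window + 1:
        raise ValueError("need at least 2*half_window+1 cells")
    order = np.lexsort((np.arange(n), pt))
    Xo, to = X[order], pt[order]
    lo = np.maximum(np.arange(n) - half_window, 0)
    hi = np.minimum(np.arange(n) + half_window, n - 1)
    dt = to[hi] - to[lo]
    dt[dt == 0] = np.inf  # flat stretch: zero slope
    slopes = (Xo[hi] - Xo[lo]) / dt[:, None]
    speed_sorted = np.linalg.norm(slopes, axis=1)
    speed = np.empty(n)
    speed[order] = speed_sorted
    return speed


def intersect_maturity_sets(sets: dict[str, set]) -> pd.DataFrame:
    """Exact pairwise and higher-order overlap counts for a Venn report."""
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    names = list(sets)
    rows = [{"sets": (nm,), "size": len(sets[nm])} for nm in names]
    for r in range(2, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(set(sets[nm]) for nm in combo))
            rows.append({"sets": combo, "size": len(inter)})
    out = pd.DataFrame(rows)
    out["label"] = out["sets"].map(lambda c: " & ".join(c))
    return out[["label", "sets", "size"]]
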