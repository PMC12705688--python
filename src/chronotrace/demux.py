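"""Sample-barcode demultiplexing: assign cells to samples from SBC counts.

Each sample is marked by a designed pair of barcoded reporter transgenes;
detection of the designed pair in a cell's barcode UMI counts is the basis
for assigning its sample of origin.  The operational rule requires (i) both
barcodes of the pair detected at a minimum UMI count, (ii) the pair's UMI
sum to dominate the best competing pair by a margin, and (iii) a purity
floor (designed-pair UMIs over total barcode UMIs).  All three thresholds
are configurable.  Correlation-based QC verifies that cotransfected pairs
are near-perfectly correlated across cells while independently
electroporated barcodes are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from ._utils import percent

__all__ = [
    "BarcodeDesign",
    "SampleAssignment",
    "assign_samples",
    "barcode_correlation",
    "demux_qc",
    "demux_summary",
]


@dataclass
class BarcodeDesign:
    """Sample -> designed barcode pair, with optional times and exclusions."""

    pairs: dict[str, tuple[str, str]]
    times_hpf: dict[str, float] | None = None
    excluded_barcodes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for sample, (b1, b2) in self.pairs.items():
            if b1 == b2:
                raise ValueError(f"sample {sample}: pair must use two distinct barcodes")
            for b in (b1, b2):
                if b in seen:
                    raise ValueError(
                        f"barcode {b} appears in both {seen[b]} and {sample}; "
                        "pairs must be disjoint")
                seen[b] = sample

    @classmethod
    def from_frame(cls, df: pd.DataFrame, excluded: list[str] | None = None) -> "BarcodeDesign":
        """From a design table with columns sample_id, barcode_id_1,
        barcode_id_2 and optionally time_hpf."""
        pairs = {str(r["sample_id"]): (str(r["barcode_id_1"]), str(r["barcode_id_2"]))
                 for _, r in df.iterrows()}
        times = None
        if "time_hpf" in df.columns:
            times = {str(r["sample_id"]): float(r["time_hpf"]) for _, r in df.iterrows()}
        return cls(pairs, times, excluded or [])

    def active_pairs(self) -> dict[str, tuple[str, str]]:
        """Pairs after dropping samples touching an excluded barcode."""
        excl = set(self.excluded_barcodes)
        return {s: p for s, p in self.pairs.items() if not (set(p) & excl)}

    def barcodes(self) -> list[str]:
        out = []
        for b1, b2 in self.active_pairs().values():
            out.extend((b1, b2))
        return out


def _counts_frame(counts) -> pd.DataFrame:
    if isinstance(counts, ad.AnnData):
        X = counts.X
        X = X.toarray() if hasattr(X, "toarray") else np.asarray(X)
        return pd.DataFrame(X, index=counts.obs_names, columns=counts.var_names)
    return pd.DataFrame(counts)


def assign_samples(
    counts,
    design: BarcodeDesign,
    min_umi_per_barcode: int = 1,
    min_purity: float = 0.6,
    margin: float = 2.0,
    require_both: bool = True,
) -> pd.DataFrame:
    """Assign each cell to a sample from its barcode UMI counts.

    A cell is assigned to sample s iff: both barcodes of s (or either, when
    ``require_both=False``) carry >= ``min_umi_per_barcode`` UMIs; the
    pair's UMI sum is >= ``margin`` times the best competing pair's sum;
    and the pair's purity (pair UMIs / total barcode UMIs) is >=
    ``min_purity``.  Otherwise the status records the first failing rule:
    no_barcode (all zero), low_count (no pair detected), ambiguous (margin
    or purity failure).

    Returns a frame indexed by cell with columns sample_id, status,
    pair_umi_sum, purity, and time_hpf when the design carries times.
    """
    df = _counts_frame(counts)
    if df.shape[0] == 0:
        raise ValueError("empty barcode count matrix")
    pairs = design.active_pairs()
    missing = [b for b in design.barcodes() if b not in df.columns]
    if missing:
        raise KeyError(f"design barcodes absent from count matrix: {missing}")
    samples = list(pairs)
    b1 = df[[pairs[s][0] for s in samples]].to_numpy(float)
    b2 = df[[pairs[s][1] for s in samples]].to_numpy(float)
    pair_sums = b1 + b2                      # cells x samples
    detected = ((b1 >= min_umi_per_barcode) & (b2 >= min_umi_per_barcode)
                if require_both else
                (b1 >= min_umi_per_barcode) | (b2 >= min_umi_per_barcode))
    total = df.to_numpy(float).sum(axis=1)

    n = df.shape[0]
    sample_out = np.array([""] * n, dtype=object)
    status = np.array(["unassigned"] * n, dtype=object)
    best_sum = np.zeros(n)
    purity = np.full(n, np.nan)

    eligible = np.where(detected, pair_sums, -np.inf)
    best_idx = np.argmax(eligible, axis=1)
    best_val = eligible[np.arange(n), best_idx]
    runner = pair_sums.copy()
    runner[np.arange(n), best_idx] = -np.inf
    runner_val = np.max(runner, axis=1)

    for i in range(n):
        if total[i] == 0:
            status[i] = "no_barcode"
            continue
        if not np.isfinite(best_val[i]):
            status[i] = "low_count"
            continue
        psum = pair_sums[i, best_idx[i]]
        best_sum[i] = psum
        purity[i] = psum / total[i]
        competing = max(runner_val[i], 0.0)
        if competing > 0 and psum < margin * competing:
            status[i] = "ambiguous"
            continue
        if purity[i] < min_purity:
            status[i] = "ambiguous"
            continue
        sample_out[i] = samples[best_idx[i]]
        status[i] = "assigned"

    out = pd.DataFrame({
        "sample_id": pd.Series(sample_out, index=df.index).replace("", pd.NA),
        "status": status,
        "pair_umi_sum": best_sum,
        "purity": purity,
    }, index=df.index)
    if design.times_hpf:
        out["time_hpf"] = out["sample_id"].map(
            lambda s: design.times_hpf.get(s) if isinstance(s, str) else np.nan)
    return out


def barcode_correlation(counts, transform: str = "log1p") -> pd.DataFrame:
    """Barcode x barcode Pearson correlation across cells.

    ``log1p`` (default) applies log1p to the counts, which stabilizes
    Pearson on sparse counts while preserving the shared per-cell reporter
    load that makes cotransfected pairs co-vary.  ``log1p_cpm`` additionally
    depth-normalizes each cell to 10k first — note that normalizing within
    the barcode compartment is compositional (the designed pair dominates a
    cell's total), which suppresses pair correlations; it is offered for
    inspecting relative barcode usage, not for pair QC.  ``raw`` correlates
    counts directly.  Zero-variance columns yield NaN (flagged missing);
    the diagonal is 1 where defined.
    """
    df = _counts_frame(counts)
    if df.shape[0] < 2:
        raise ValueError("need at least 2 cells for correlation")
    if transform == "log1p":
        mat = np.log1p(df.astype(float))
    elif transform == "log1p_cpm":
        total = df.sum(axis=1)
        scaled = df.div(total.replace(0, np.nan), axis=0) * 1e4
        mat = np.log1p(scaled.fillna(0.0))
    elif transform == "raw":
        mat = df.astype(float)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return mat.corr(method="pearson")


def demux_qc(
    corr: pd.DataFrame,
    design: BarcodeDesign,
    pair_min: float = 0.98,
    cross_max: float = 0.05,
) -> dict:
    """QC report: designed-pair correlations vs. cross-pair leakage.

    Flags each cotransfected pair whose correlation reaches ``pair_min``
    and each cross-pair (barcodes from different samples) staying under
    ``cross_max``.  The cross check uses the *signed* maximum: leakage
    manifests as positive correlation, whereas mutual exclusivity between
    samples makes mild anticorrelation expected.  Failing barcodes are
    listed for exclusion upstream.
    """
    pairs = design.active_pairs()
    for b in design.barcodes():
        if b not in corr.index:
            raise KeyError(f"correlation matrix missing designed barcode {b}")
    pair_rows = []
    for sample, (x, y) in pairs.items():
        r = corr.loc[x, y]
        pair_rows.append({"sample_id": sample, "barcode_1": x, "barcode_2": y,
                          "correlation": float(r),
                          "passes": bool(np.isfinite(r) and r >= pair_min)})
    cross_rows = []
    items = list(pairs.items())
    for i, (s1, p1) in enumerate(items):
        for s2, p2 in items[i + 1:]:
            sub = corr.loc[list(p1), list(p2)].to_numpy(float)
            worst = float(np.nanmax(sub))
            cross_rows.append({"sample_a": s1, "sample_b": s2,
                               "max_correlation": worst,
                               "passes": worst < cross_max})
    failing = sorted({r["barcode_1"] for r in pair_rows if not r["passes"]}
                     | {r["barcode_2"] for r in pair_rows if not r["passes"]})
    return {
        "pair_correlations": pair_rows,
        "cross_pair": cross_rows,
        "failing_barcodes": failing,
        "all_pairs_pass": all(r["passes"] for r in pair_rows),
        "all_cross_pass": all(r["passes"] for r in cross_rows),
        "pair_min": pair_min,
        "cross_max": cross_max,
    }


def demux_summary(assignment: pd.DataFrame) -> dict:
    """Assignment summary with half-up one-decimal percentage."""
    n_total = int(len(assignment))
    if n_total == 0:
        raise ValueError("empty assignment")
    assigned = assignment["status"] == "assigned"
    n_assigned = int(assigned.sum())
    per_sample = (assignment.loc[assigned, "sample_id"].value_counts().sort_index()
                  .astype(int).to_dict())
    return {
        "n_total": n_total,
        "n_assigned": n_assigned,
        "percent_assigned": percent(n_assigned, n_total, 1),
        "per_sample": per_sample,
        "status_counts": assignment["status"].value_counts().astype(int).to_dict(),
    }
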