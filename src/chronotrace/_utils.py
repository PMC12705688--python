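"""Small shared helpers: seeding, half-up rounding, deterministic k-NN."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.spatial.distance import cdist


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (5 rounds up).

    Python's builtin ``round`` uses banker's rounding; reported percentages
    use the conventional half-up rule instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(k: int, n: int, ndigits: int = 1) -> float:
    """100*k/n rounded half-up, computed in decimal to avoid float artifacts."""
    if n == 0:
        raise ValueError("percent undefined for n = 0")
    q = Decimal(1).scaleb(-ndigits)
    return float((Decimal(k) * 100 / Decimal(n)).quantize(q, rounding=ROUND_HALF_UP))


def derive_seed(seed: int, offset: int) -> int:
    """Fan a global seed out to per-stage seeds; result stays below 2**31."""
    return (int(seed) * 9973 + offset * 7919 + 1) % (2**31 - 1)


def knn_indices(
    query: np.ndarray,
    reference: np.ndarray,
    k: int,
    exclude_identity: np.ndarray | None = None,
    metric: str = "euclidean",
) -> tuple[np.ndarray, np.ndarray]:
    """Exact k nearest neighbors of ``query`` rows among ``reference`` rows.

    Ties in distance are broken by reference row index (ascending), which
    makes the graph deterministic — a contract the downstream median voting
    relies on.  ``exclude_identity[i]`` (optional) is a reference index to
    drop for query ``i`` (self-exclusion in leave-one-out settings).

    Returns (indices, distances), each of shape (n_query, k).
    """
    query = np.asarray(query, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if query.ndim == 1:
        query = query[:, None]
    if reference.ndim == 1:
        reference = reference[:, None]
    n_ref = reference.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    d = cdist(query, reference, metric=metric)
    if exclude_identity is not None:
        rows = np.arange(d.shape[0])
        mask = np.asarray(exclude_identity) >= 0
        d[rows[mask], np.asarray(exclude_identity)[mask]] = np.inf
        avail = n_ref - 1
    else:
        avail = n_ref
    if k > avail:
        raise ValueError(f"k={k} exceeds available reference points ({avail})")
    # lexsort: primary key distance, secondary key index -> deterministic ties
    idx = np.arange(n_ref)
    order = np.lexsort((np.broadcast_to(idx, d.shape), d), axis=1)[:, :k]
    dists = np.take_along_axis(d, order, axis=1)
    return order, dists
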