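"""Division-orientation and asymmetry statistics from 3D cell centroids.

Segmented half-embryos yield a handful of labeled cell centroids (and
optionally volumes).  Division orientation is summarized by the minimum
absolute cosine over all pairs of axes formed within cell triplets — a
dimensionless, rigid-motion-invariant statistic that drops toward 0 when
some division axis turns orthogonal to the others and equals 1 only for
collinear configurations.  Division asymmetry is the smaller/larger sister
volume ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "CentroidSet",
    "min_triplet_cosine",
    "triplet_cosine_table",
    "asymmetry_ratio",
    "orientation_class",
]

_EPS = 1e-12


@dataclass
class CentroidSet:
    """Labeled 3D centroids for one half-embryo.

    ``points`` is (n, 3) in any consistent length unit; statistics are
    dimensionless.  Optional per-cell ``volumes`` must be positive.
    Reference axes (embryo midline-normal i.e. mediolateral, and
    anteroposterior) are unit-normalized on construction when given.
    """

    points: np.ndarray
    labels: list[str] | None = None
    volumes: np.ndarray | None = None
    mediolateral_axis: np.ndarray | None = None
    anteroposterior_axis: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if self.points.shape[0] < 2:
            raise ValueError("need at least 2 points")
        if self.labels is None:
            self.labels = [f"cell{i}" for i in range(self.points.shape[0])]
        if self.volumes is not None:
            self.volumes = np.asarray(self.volumes, dtype=float)
            if np.any(self.volumes <= 0):
                raise ValueError("volumes must be positive")
        for attr in ("mediolateral_axis", "anteroposterior_axis"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=float)
                nrm = np.linalg.norm(v)
                if nrm < _EPS:
                    raise ValueError(f"{attr} has zero length")
                setattr(self, attr, v / nrm)


def _abs_cos(u: np.ndarray, v: np.ndarray) -> float:
    return abs(float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v)))


def triplet_cosine_table(points: CentroidSet | np.ndarray) -> pd.DataFrame:
    """Per-triplet minimum |cos| between the three within-triplet axes.

    Each unordered triplet (i, j, k) defines three axes (the pairwise
    difference vectors); all three axis pairs are compared by absolute
    cosine.  Zero-length axes (coincident points) are skipped.
    """
    pts = points.points if isinstance(points, CentroidSet) else np.asarray(points, float)
    n = pts.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for triplet statistics")
    rows = []
    for i, j, k in combinations(range(n), 3):
        axes = [pts[j] - pts[i], pts[k] - pts[i], pts[k] - pts[j]]
        axes = [a for a in axes if np.linalg.norm(a) > _EPS]
        cosines = [_abs_cos(u, v) for u, v in combinations(axes, 2)]
        if cosines:
            rows.append({"i": i, "j": j, "k": k, "min_abs_cos": min(cosines)})
    return pd.DataFrame(rows)


def min_triplet_cosine(points: CentroidSet | np.ndarray) -> float:
    """Minimum |cos| over all axis pairs within all cell triplets, in [0, 1].

    Invariant under rigid transforms and uniform scaling; 1.0 iff all
    points are collinear.  Degenerate axes from coincident points are
    skipped; an error is raised if every axis degenerates.
    """
    table = triplet_cosine_table(points)
    if table.empty:
        raise ValueError("all triplet axes are degenerate (coincident points)")
    return float(table["min_abs_cos"].min())


def asymmetry_ratio(volumes, threshold: float = 0.8) -> tuple[float, str]:
    """Sister-cell volume ratio smaller/larger in (0, 1].

    Classified ``asymmetric`` when the ratio falls strictly below
    ``threshold`` (default 0.8), else ``symmetric``.
    """
    v = np.asarray(volumes, dtype=float)
    if v.shape != (2,):
        raise ValueError("expected exactly two volumes")
    if np.any(v <= 0):
        raise ValueError("volumes must be positive")
    ratio = float(v.min() / v.max())
    return ratio, ("asymmetric" if ratio < threshold else "symmetric")


def orientation_class(
    sister_axis,
    mediolateral_axis,
    anteroposterior_axis,
    oblique_max_cos: float = 0.5 * np.sqrt(2.0),
) -> str:
    """Classify a sister-pair division axis against embryo reference axes.

    The axis is assigned to whichever reference direction has the larger
    |cos|; when neither |cos| exceeds the margin (default cos 45° = √2/2,
    so an exact 45° axis is already oblique) the division is ``oblique``.
    """
    axis = np.asarray(sister_axis, dtype=float)
    if np.linalg.norm(axis) < _EPS:
        raise ValueError("sister axis has zero length")
    ml = np.asarray(mediolateral_axis, dtype=float)
    ap = np.asarray(anteroposterior_axis, dtype=float)
    if np.linalg.norm(ml) < _EPS or np.linalg.norm(ap) < _EPS:
        raise ValueError("reference axes required")
    if _abs_cos(ml, ap) > 1 - 1e-9:
        raise ValueError("reference axes must not be parallel")
    cos_ml = _abs_cos(axis, ml)
    cos_ap = _abs_cos(axis, ap)
    if max(cos_ml, cos_ap) <= oblique_max_cos + 1e-12:
        return "oblique"
    return "mediolateral" if cos_ml >= cos_ap else "anteroposterior"


def analyze_centroid_table(df: pd.DataFrame, threshold: float = 0.8) -> pd.DataFrame:
    """Per-embryo geometry summary from a long table.

    Expects columns embryo_id, cell_label, x, y, z and optionally volume.
    Emits min-triplet-cosine per embryo (when >= 3 cells) and the volume
    asymmetry ratio of the two largest cells when volumes are present.
    """
    out = []
    for embryo, grp in df.groupby("embryo_id", sort=True):
        pts = grp[["x", "y", "z"]].to_numpy(float)
        rec: dict = {"embryo_id": embryo, "n_cells": len(grp)}
        if len(grp) >= 3:
            try:
                rec["min_triplet_cosine"] = min_triplet_cosine(pts)
            except ValueError:
                rec["min_triplet_cosine"] = np.nan
        if "volume" in grp.columns and grp["volume"].notna().sum() >= 2:
            top = grp["volume"].dropna().nlargest(2).to_numpy()
            ratio, cls = asymmetry_ratio(top, threshold)
            rec["volume_ratio"] = ratio
            rec["asymmetry_class"] = cls
        out.append(rec)
    return pd.DataFrame(out)
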