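"""Clinical cosmesis metrics on 2D breast contours.

Three easy measurements track the phases of healing: the vertical nipple
height difference between the treated and control breast, the breast area
inside a fixed-radius disc centered on the nipple (a 2D surrogate for
breast volume), and the principal dimensions of the wound cavity.  A
simple change-point segmentation recovers the three healing phases from a
metric time series.  Temperature series carry no model and are handled as
plain data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from shapely.geometry import Point, Polygon

__all__ = ["MetricSeries", "CavityDims", "nipple_point",
           "nipple_height_difference", "lateral_disc_area",
           "cavity_dimensions", "phase_classifier", "PhaseSegmentation"]

#: Healing-phase boundaries (weeks post-surgery): Phase I weeks 1-6,
#: Phase II weeks 7-20, Phase III weeks 21-35.
PHASE_BOUNDARIES_WEEKS = (6.5, 20.5)


@dataclass
class MetricSeries:
    """A metric sampled over the follow-up (weeks post surgery)."""

    weeks: np.ndarray
    values: np.ndarray
    name: str = ""
    unit: str = ""

    def __post_init__(self):
        self.weeks = np.asarray(self.weeks, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.weeks) <= 0):
            raise ValueError("times must be strictly increasing")

    def phase_labels(self) -> np.ndarray:
        b1, b2 = PHASE_BOUNDARIES_WEEKS
        return np.where(self.weeks <= b1, "I",
                        np.where(self.weeks <= b2, "II", "III"))

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"week": self.weeks, "value": self.values,
                      "phase": self.phase_labels()}).to_csv(path,
                                                            index=False)


def nipple_point(contour: np.ndarray) -> np.ndarray:
    """Nipple landmark: the most anterior contour point (max x; ties to
    the lowest y)."""
    pts = np.asarray(contour, dtype=float)
    xmax = pts[:, 0].max()
    if xmax - pts[:, 0].min() < 1e-9:
        raise ValueError("flat contour: nipple landmark undetectable")
    cand = pts[np.abs(pts[:, 0] - xmax) < 1e-9]
    return cand[np.argmin(cand[:, 1])]


def nipple_height_difference(contour_treated: np.ndarray,
                             contour_control: np.ndarray) -> float:
    """Absolute vertical nipple height difference (mm)."""
    return float(abs(nipple_point(contour_treated)[1]
                     - nipple_point(contour_control)[1]))


def lateral_disc_area(contour: np.ndarray, nipple=None,
                      radius: float = 60.0) -> float:
    """Breast area (cm^2) within a disc of given radius about the nipple."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    pts = np.asarray(contour, dtype=float)
    breast = Polygon(pts)
    if not breast.is_valid:
        breast = breast.buffer(0)
    p = nipple_point(pts) if nipple is None else np.asarray(nipple)
    if not breast.buffer(1e-6).contains(Point(p)):
        raise ValueError("nipple lies outside the breast region")
    disc = Point(p).buffer(radius, quad_segs=256)
    return float(breast.intersection(disc).area) / 100.0


class CavityDims(NamedTuple):
    major: float          # mm
    minor: float          # mm
    closed: bool


def cavity_dimensions(source) -> CavityDims:
    """Principal axis lengths of the (possibly deformed) cavity boundary.

    ``source`` may be a shapely polygon, an (N, 2) point array, a
    BreastMesh, or a MechanicalState (whose deformed cavity-wall nodes are
    used).  Lengths are the extents along the principal directions of the
    boundary point cloud — exact for an ellipse.  A closed wound returns
    zero dimensions with the ``closed`` flag set.
    """
    from .mechanics import MechanicalState
    from .mesh import BreastMesh

    if isinstance(source, MechanicalState):
        ids = source.mesh.boundary_nodes("cavity_wall")
        if len(ids) == 0:
            return CavityDims(0.0, 0.0, True)
        pts = source.deformed_nodes[ids]
    elif isinstance(source, BreastMesh):
        ids = source.boundary_nodes("cavity_wall")
        if len(ids) == 0:
            return CavityDims(0.0, 0.0, True)
        pts = source.nodes[ids]
    elif isinstance(source, Polygon):
        if source.is_empty:
            return CavityDims(0.0, 0.0, True)
        pts = np.asarray(source.exterior.coords)
    else:
        pts = np.asarray(source, dtype=float)
        if pts.size == 0:
            return CavityDims(0.0, 0.0, True)
    pts = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    proj = pts @ vt.T
    ext = proj.max(axis=0) - proj.min(axis=0)
    major, minor = float(ext.max()), float(ext.min())
    return CavityDims(major, minor, False)


@dataclass
class PhaseSegmentation:
    breakpoints: tuple[float, float] | None    # weeks
    degenerate: bool
    reason: str = ""


def phase_classifier(series: MetricSeries) -> PhaseSegmentation:
    """Three-segment change-point estimate of the healing phases.

    Fits an independent linear trend on each of three contiguous segments
    and exhaustively searches the two break positions minimising the
    residual sum of squares.  Monotone or constant series carry no phase
    structure and are flagged degenerate.
    """
    w, v = series.weeks, series.values
    n = len(w)
    if n < 5:
        raise ValueError("need at least 5 time points")
    if np.ptp(v) < 1e-12:
        return PhaseSegmentation(None, True, "constant series")

    def sse(i, j):
        x, y = w[i:j], v[i:j]
        if len(x) < 2:
            return np.inf
        A = np.column_stack([x, np.ones_like(x)])
        coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
        r = y - A @ coef
        return float(r @ r), float(coef[0])

    best, best_k = np.inf, None
    for k1 in range(2, n - 3):
        for k2 in range(k1 + 2, n - 1):
            s1, sl1 = sse(0, k1)
            s2, sl2 = sse(k1, k2)
            s3, sl3 = sse(k2, n)
            tot = s1 + s2 + s3
            if tot < best:
                best, best_k, slopes = tot, (k1, k2), (sl1, sl2, sl3)
    if best_k is None:
        return PhaseSegmentation(None, True, "series too short to segment")
    signs = np.sign(slopes)
    if signs[0] == signs[1] == signs[2] and signs[0] != 0:
        return PhaseSegmentation(None, True, "monotone series")
    k1, k2 = best_k
    bp = (float((w[k1 - 1] + w[k1]) / 2), float((w[k2 - 1] + w[k2]) / 2))
    return PhaseSegmentation(bp, False)
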