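"""Image-processing stages of the virtual breast reconstruction.

Three operations mirror the study's MRI pipeline: fuzzy C-means (FCM)
intensity segmentation into background / fat / glandular classes, 1D
Tikhonov smoothing of the skin interface profile, and sub-pixel contour
extraction from a binary silhouette.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve
from skimage import measure

__all__ = ["FCMResult", "SkinProfile", "fuzzy_cmeans", "fcm_objective",
           "tikhonov_smooth", "skin_profile", "extract_contour",
           "contour_area"]


@dataclass
class FCMResult:
    """Fuzzy C-means output on a grayscale image.

    ``membership[k]`` is the fuzzy membership map of class ``k`` (classes
    ordered by ascending centroid intensity, so class 0 is the darkest —
    background for MRI-like images); memberships sum to one per pixel and
    ``labels`` is their argmax.
    """

    membership: np.ndarray        # (n_classes, ny, nx), values in [0, 1]
    labels: np.ndarray            # (ny, nx) hard assignment
    centroids: np.ndarray         # (n_classes,) ascending intensities
    iterations: int
    final_shift: float            # last centroid movement


def _init_centroids(values: np.ndarray, n_classes: int,
                    rng: np.random.Generator) -> np.ndarray:
    qs = (np.arange(n_classes) + 0.5) / n_classes * 100.0
    c = np.percentile(values, qs)
    spread = values.std() + 1e-9
    c = c + rng.normal(0.0, 0.01 * spread, size=n_classes)
    return np.sort(c)


def fuzzy_cmeans(image: np.ndarray, n_classes: int = 3, m: float = 2.0,
                 tol: float = 1e-5, max_iter: int = 300,
                 seed: int = 0) -> FCMResult:
    """Segment a grayscale image by fuzzy C-means on pixel intensities.

    Standard FCM fixed-point iteration: memberships
    u_ik = 1 / sum_j (d_ik / d_jk)^(2/(m-1)), centroids as the u^m-weighted
    means; stops when the largest centroid movement drops below ``tol``.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if m <= 1:
        raise ValueError("fuzziness m must be > 1")
    x = img.ravel()
    if len(np.unique(x)) < n_classes:
        raise ValueError("fewer distinct intensities than classes")

    rng = np.random.default_rng(seed)
    c = _init_centroids(x, n_classes, rng)
    expo = 2.0 / (m - 1.0)
    it, shift = 0, np.inf
    u = None
    for it in range(1, max_iter + 1):
        d = np.abs(x[None, :] - c[:, None])
        exact = d < 1e-12
        d = np.maximum(d, 1e-12)
        w = d ** (-expo)
        u = w / w.sum(axis=0, keepdims=True)
        # pixels sitting exactly on a centroid get crisp membership
        hit = exact.any(axis=0)
        if hit.any():
            u[:, hit] = exact[:, hit].astype(float)
            u[:, hit] /= u[:, hit].sum(axis=0, keepdims=True)
        um = u ** m
        c_new = um @ x / um.sum(axis=1)
        c_new = np.sort(c_new)
        shift = float(np.max(np.abs(c_new - c)))
        c = c_new
        if shift < tol:
            break
    d = np.maximum(np.abs(x[None, :] - c[:, None]), 1e-12)
    w = d ** (-expo)
    u = w / w.sum(axis=0, keepdims=True)
    labels = u.argmax(axis=0).reshape(img.shape)
    return FCMResult(membership=u.reshape((n_classes,) + img.shape),
                     labels=labels, centroids=c, iterations=it,
                     final_shift=shift)


def fcm_objective(image: np.ndarray, result: FCMResult, m: float = 2.0) -> float:
    """Weighted within-class distance sum_ik u_ik^m d_ik^2 (monitoring)."""
    x = np.asarray(image, dtype=float).ravel()
    u = result.membership.reshape(len(result.centroids), -1)
    d2 = (x[None, :] - result.centroids[:, None]) ** 2
    return float(np.sum(u ** m * d2))


@dataclass
class SkinProfile:
    """Per-row skin elevation samples along the chest wall direction."""

    values: np.ndarray        # mm, anterior skin position per sample
    spacing: float            # mm between samples (= pixel pitch)


def tikhonov_smooth(profile: SkinProfile | np.ndarray, lam: float):
    """Second-difference (curvature) Tikhonov smoother, solved exactly.

    Returns argmin_u ||u - d||^2 + lam * ||D2 u||^2 with natural boundary
    conditions; lam = 0 reproduces the input and constant inputs are fixed
    points for any lam (D2's null space).
    """
    if lam < 0:
        raise ValueError("regularization weight must be >= 0")
    arr = profile.values if isinstance(profile, SkinProfile) else profile
    d = np.asarray(arr, dtype=float)
    if d.ndim != 1 or len(d) < 3:
        raise ValueError("profile needs at least 3 samples")
    if not np.all(np.isfinite(d)):
        raise ValueError("profile contains non-finite samples")
    n = len(d)
    main = np.ones(n)
    D2 = sparse.diags([main[:-2], -2 * main[:-2], main[:-2]], [0, 1, 2],
                      shape=(n - 2, n), format="csr")
    A = sparse.eye(n, format="csr") + lam * (D2.T @ D2)
    u = spsolve(A.tocsc(), d)
    if isinstance(profile, SkinProfile):
        return SkinProfile(values=u, spacing=profile.spacing)
    return u


def skin_profile(label_map) -> SkinProfile:
    """Anterior skin elevation per row of a tissue label map (mm)."""
    mask = label_map.foreground_mask()
    ny, nx = mask.shape
    elev = np.full(ny, np.nan)
    for iy in range(ny):
        idx = np.nonzero(mask[iy])[0]
        if len(idx):
            elev[iy] = label_map.origin[0] + (idx[-1] + 1.0) * label_map.pixel_pitch
    rows = np.isfinite(elev)
    return SkinProfile(values=elev[rows], spacing=label_map.pixel_pitch)


def extract_contour(source, include_chest: bool = True) -> np.ndarray:
    """Closed sub-pixel contour (mm) of a single-component silhouette.

    ``source`` is a :class:`~bctsim.phantom.TissueLabelMap` (its breast
    tissue mask, optionally with the chest band) or a tuple
    ``(mask, pitch, origin)``.  Marching squares at level 0.5 on a
    zero-padded grid guarantees a closed polyline; exactly one foreground
    component is required.
    """
    from .phantom import TissueLabelMap, CHEST

    if isinstance(source, TissueLabelMap):
        mask = source.foreground_mask()
        if include_chest:
            mask = mask | (source.grid == CHEST)
        pitch, origin = source.pixel_pitch, source.origin
    else:
        mask, pitch, origin = source
        mask = np.asarray(mask, dtype=bool)

    n_comp = ndimage.label(mask)[1]
    if n_comp == 0:
        raise ValueError("no foreground component")
    if n_comp > 1:
        raise ValueError(f"expected one foreground component, found {n_comp}")

    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    contours.sort(key=len, reverse=True)
    c = contours[0]                       # (row, col) in padded index space
    x = origin[0] + (c[:, 1] - 1 + 0.5) * pitch
    y = origin[1] + (c[:, 0] - 1 + 0.5) * pitch
    pts = np.column_stack([x, y])
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    return pts


def contour_area(contour: np.ndarray) -> float:
    """Shoelace area of a closed polyline (mm^2)."""
    p = np.asarray(contour, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)
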