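"""Synthetic 2D breast phantoms.

Generates sagittal breast cross-sections as tissue label maps, MRI-like
grayscale images and noisy "observed" breast contours, emulating the data a
single-patient breast-conserving-therapy (BCT) study acquires: a prone MRI
slice segmented into fat / glandular tissue / skin on the chest wall, and
side-view photographs of the breast silhouette.

Conventions
-----------
* Coordinates are in mm; ``x`` points anterior (away from the chest wall),
  ``y`` points superior (up when the patient is seated).  The chest band
  occupies ``0 <= x <= chest_depth`` and the breast protrudes from it.
* Label maps are stored as ``grid[iy, ix]`` with row 0 at the bottom
  (``y = 0``); pixel centers sit at ``origin + (i + 0.5) * pitch``.
* Randomness: one master seed; every stage derives its own independent
  stream via :func:`rng_for`, so stages can be re-run in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from shapely.geometry import Point, Polygon

__all__ = [
    "BACKGROUND", "FAT", "GLANDULAR", "SKIN", "CHEST", "LABEL_NAMES",
    "PhantomSpec", "TissueLabelMap", "SyntheticObservation",
    "generate_phantom", "generate_mri_image", "generate_observation",
    "rng_for", "write_pgm", "read_pgm", "write_contour_csv",
    "read_contour_csv",
]

# Tissue label codes shared across the package.
BACKGROUND, FAT, GLANDULAR, SKIN, CHEST = 0, 1, 2, 3, 4
LABEL_NAMES = {BACKGROUND: "background", FAT: "fat", GLANDULAR: "glandular",
               SKIN: "skin", CHEST: "chest"}

#: MRI in-plane pixel pitch of the study data (mm).
MRI_PITCH = 0.7031


def rng_for(seed: int, *keys: str) -> np.random.Generator:
    """Derive an independent, reproducible stream from a master seed.

    Stage names are hashed (CRC32) into the seed sequence so each pipeline
    stage gets its own stream while remaining a pure function of
    ``(seed, keys)``.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy += [zlib.crc32(k.encode()) & 0x7FFFFFFF for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass
class PhantomSpec:
    """Geometry and composition of a synthetic sagittal breast slice.

    The defaults reproduce the geometry reported for the study patient: an
    ellipsoidal tumor bed of 12 x 9 mm centered 47 mm deep from the skin,
    above the nipple, imaged at 0.7031 mm pixel pitch with a 1 mm skin.
    """

    chest_wall_length: float = 120.0     # mm, vertical extent of the slice
    breast_protrusion: float = 65.0      # mm, anterior semi-axis of the outline
    glandular_fraction: float = 0.25     # fraction of the interior (fat+glandular)
    skin_thickness: float = 1.0          # mm
    tumor_center: tuple[float, float] | None = None   # mm; None -> from depth rule
    tumor_axes: tuple[float, float] = (12.0, 9.0)     # full axes, mm
    tumor_depth: float = 47.0            # mm from the skin, along -x
    nipple_position: tuple[float, float] | None = None
    pixel_pitch: float = MRI_PITCH       # mm
    chest_depth: float = 3.0             # mm, thickness of the meshed chest band
    outline_perturbation: float = 0.02   # relative radial roughness of the outline
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.glandular_fraction < 1.0):
            raise ValueError("glandular_fraction must be in [0, 1)")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.skin_thickness <= 0:
            raise ValueError("skin_thickness must be positive")

    # -- derived geometry ---------------------------------------------------
    def outline(self, n: int = 720) -> np.ndarray:
        """Perturbed half-ellipse outline of the breast (open polyline).

        Runs from the inferior chest attachment to the superior one; the
        radial perturbation is windowed by cos^2(theta) so the attachment
        points stay fixed on the chest band.
        """
        a = self.breast_protrusion
        b = self.chest_wall_length / 2.0
        yc = self.chest_wall_length / 2.0
        theta = np.linspace(-np.pi / 2, np.pi / 2, n)
        rho = np.ones_like(theta)
        rng = rng_for(self.rng_seed, "outline")
        for k in (2, 3, 4):
            amp = rng.normal(0.0, self.outline_perturbation)
            phase = rng.uniform(0, 2 * np.pi)
            rho += amp * np.cos(k * theta + phase) * np.cos(theta) ** 2
        x = self.chest_depth + a * rho * np.cos(theta)
        y = yc + b * rho * np.sin(theta)
        return np.column_stack([x, y])

    def outline_polygon(self) -> Polygon:
        """Breast outline closed along the chest interface."""
        pts = self.outline()
        closed = np.vstack([pts, [[self.chest_depth, pts[-1, 1]],
                                  [self.chest_depth, pts[0, 1]]]])
        return Polygon(closed)

    def nipple(self) -> tuple[float, float]:
        if self.nipple_position is not None:
            return self.nipple_position
        pts = self.outline()
        i = int(np.argmax(pts[:, 0]))
        return float(pts[i, 0]), float(pts[i, 1])

    def tumor_centre(self) -> tuple[float, float]:
        """Tumor bed center: 47 mm deep from the skin, above the nipple."""
        if self.tumor_center is not None:
            return self.tumor_center
        nx, ny = self.nipple()
        return (nx - self.tumor_depth, ny + 15.0)

    def tumor_polygon(self) -> Polygon:
        cx, cy = self.tumor_centre()
        ax, ay = self.tumor_axes[0] / 2.0, self.tumor_axes[1] / 2.0
        circ = Point(cx, cy).buffer(1.0, quad_segs=64)
        from shapely import affinity
        return affinity.scale(circ, ax, ay)

    def to_json(self, path: str | Path) -> None:
        import json
        from dataclasses import asdict
        Path(path).write_text(json.dumps(asdict(self), indent=2,
                                         sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        import json
        data = json.loads(Path(path).read_text())
        for key in ("tumor_center", "tumor_axes", "nipple_position"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def validate_geometry(self) -> None:
        """Raise if the tumor bed is not strictly interior to the breast."""
        clearance = self.skin_thickness + 2.0
        interior = self.outline_polygon().buffer(-clearance)
        if not interior.contains(self.tumor_polygon()):
            raise ValueError(
                "tumor ellipse not strictly inside the breast interior "
                f"(needs {clearance:.1f} mm clearance from the boundary)")


@dataclass
class TissueLabelMap:
    """2D grid of tissue class labels with physical pixel geometry."""

    grid: np.ndarray                  # (ny, nx) uint8 of label codes
    pixel_pitch: float                # mm
    origin: tuple[float, float] = (0.0, 0.0)   # mm, lower-left pixel corner

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.grid.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.pixel_pitch
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.pixel_pitch
        return x, y

    def label_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-pixel label lookup at physical points (mm)."""
        ny, nx = self.grid.shape
        ix = np.clip(((np.asarray(x) - self.origin[0]) / self.pixel_pitch - 0.5)
                     .round().astype(int), 0, nx - 1)
        iy = np.clip(((np.asarray(y) - self.origin[1]) / self.pixel_pitch - 0.5)
                     .round().astype(int), 0, ny - 1)
        return self.grid[iy, ix]

    def foreground_mask(self) -> np.ndarray:
        """Breast tissue pixels (fat, glandular, skin) — excludes chest."""
        return np.isin(self.grid, (FAT, GLANDULAR, SKIN))

    def class_area(self, label: int) -> float:
        """Physical area of one tissue class (mm^2)."""
        return float(np.count_nonzero(self.grid == label)) * self.pixel_pitch ** 2


@dataclass
class SyntheticObservation:
    """A noisy 'photograph' contour produced by the forward model.

    ``aspect_ratio`` mimics the unknown pixel scale of a clinical
    photograph: the stored contour equals the clean model contour divided
    by ``aspect_ratio``, so the calibration's scale nuisance ``s`` recovers
    it (``f(alpha_true, s=aspect_ratio) = 0`` for a noiseless observation).
    """

    phase: str                       # one of "0", "I", "II", "III"
    contour: np.ndarray              # (N, 2) mm polyline, closure implied
    true_params: dict = field(default_factory=dict)
    noise_sd: float = 0.0            # mm, along local normals
    aspect_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.phase not in ("0", "I", "II", "III"):
            raise ValueError(f"unknown phase {self.phase!r}")


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> TissueLabelMap:
    """Rasterize a PhantomSpec into a tissue label map.

    Deterministic for a fixed ``spec.rng_seed``.  Glandular tissue is laid
    down as a smoothed Gaussian random field biased toward the retro-areolar
    region (behind the nipple) and thresholded at the quantile that makes
    glandular pixels occupy exactly ``glandular_fraction`` of the interior
    (fat + glandular) up to pixelation.
    """
    spec.validate_geometry()
    pitch = spec.pixel_pitch
    width = spec.chest_depth + spec.breast_protrusion * 1.15
    nx = int(np.ceil(width / pitch))
    ny = int(np.ceil(spec.chest_wall_length / pitch))
    xs = (np.arange(nx) + 0.5) * pitch
    ys = (np.arange(ny) + 0.5) * pitch
    X, Y = np.meshgrid(xs, ys)

    # analytic inside test against the perturbed half-ellipse
    a = spec.breast_protrusion
    b = spec.chest_wall_length / 2.0
    yc = spec.chest_wall_length / 2.0
    u = (X - spec.chest_depth) / a
    v = (Y - yc) / b
    theta = np.arctan2(v, np.maximum(u, 1e-12))
    rho = np.ones_like(theta)
    rng = rng_for(spec.rng_seed, "outline")
    for k in (2, 3, 4):
        amp = rng.normal(0.0, spec.outline_perturbation)
        phase = rng.uniform(0, 2 * np.pi)
        rho += amp * np.cos(k * theta + phase) * np.cos(theta) ** 2
    breast = (u >= 0) & (np.hypot(u, v) <= rho)
    chest = (X <= spec.chest_depth) & ~breast

    grid = np.full((ny, nx), BACKGROUND, dtype=np.uint8)
    grid[chest] = CHEST
    grid[breast] = FAT

    # skin band: breast pixels within skin_thickness of the background
    background = ~breast & ~chest
    dist = ndimage.distance_transform_edt(~background, sampling=pitch)
    skin = breast & (dist <= spec.skin_thickness)
    grid[skin] = SKIN

    interior = breast & ~skin
    if spec.glandular_fraction > 0:
        rng_g = rng_for(spec.rng_seed, "glandular")
        noise = rng_g.standard_normal((ny, nx))
        fld = ndimage.gaussian_filter(noise, sigma=4.0 / pitch, mode="nearest")
        fld = (fld - fld.mean()) / (fld.std() + 1e-12)
        npx, npy = spec.nipple()
        bias = np.exp(-(((X - (spec.chest_depth + 0.35 * a)) / (0.35 * a)) ** 2
                        + ((Y - npy) / (0.30 * b)) ** 2))
        z = fld + 1.2 * bias
        vals = z[interior]
        thr = np.quantile(vals, 1.0 - spec.glandular_fraction)
        grid[interior & (z > thr)] = GLANDULAR

    return TissueLabelMap(grid=grid, pixel_pitch=pitch)


def generate_mri_image(label_map: TissueLabelMap,
                       class_means: dict[int, float] | None = None,
                       noise_sd: float = 0.0,
                       seed: int = 0) -> np.ndarray:
    """8-bit-range MRI-like grayscale image from a label map.

    Each pixel is its class mean plus iid Gaussian noise, clipped to
    [0, 255].  The default intensity table gives skin and chest the fat
    intensity, matching the study's three-class MRI appearance
    (background / fat / glandular).
    """
    if class_means is None:
        class_means = {BACKGROUND: 20.0, FAT: 100.0, GLANDULAR: 180.0,
                       SKIN: 100.0, CHEST: 100.0}
    if len(set(class_means.values())) < 2:
        raise ValueError("class means must be distinct")
    grid = label_map.grid
    if grid.size == 0:
        raise ValueError("empty label map")
    img = np.zeros(grid.shape, dtype=float)
    for lab, mean in class_means.items():
        img[grid == lab] = mean
    if noise_sd > 0:
        img += rng_for(seed, "mri-noise").normal(0.0, noise_sd, size=grid.shape)
    return np.clip(img, 0.0, 255.0)


def perturb_contour(contour: np.ndarray, noise_sd: float,
                    rng: np.random.Generator,
                    freeze_x_below: float | None = None) -> np.ndarray:
    """Displace a closed polyline along its local normals.

    The per-vertex Gaussian offsets are circularly smoothed (window 5) and
    rescaled to unit variance before scaling by ``noise_sd``, mimicking the
    spatially correlated error of a silhouette segmentation while keeping
    the RMS normal deviation equal to ``noise_sd``.  Vertices with
    ``x < freeze_x_below`` (the chest-wall closure) are left in place.
    """
    if noise_sd == 0:
        return contour.copy()
    pts = np.asarray(contour, dtype=float)
    nxt = np.roll(pts, -1, axis=0)
    prv = np.roll(pts, 1, axis=0)
    tang = nxt - prv
    nrm = np.column_stack([tang[:, 1], -tang[:, 0]])
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True) + 1e-12
    eps = rng.standard_normal(len(pts))
    eps = ndimage.uniform_filter1d(eps, size=5, mode="wrap")
    eps = eps / (eps.std() + 1e-12) * noise_sd
    if freeze_x_below is not None:
        eps = np.where(pts[:, 0] < freeze_x_below, 0.0, eps)
    return pts + nrm * eps[:, None]


def generate_observation(label_map: TissueLabelMap,
                         phase: str,
                         true_params: dict,
                         noise_sd: float = 0.0,
                         aspect_ratio: float = 1.0,
                         seed: int = 0,
                         spec: PhantomSpec | None = None,
                         **simulate_kwargs) -> SyntheticObservation:
    """Run the forward model at known parameters and corrupt the contour.

    The clean contour comes from :func:`bctsim.calibration.simulate_phase`;
    it is divided by ``aspect_ratio`` (emulating an uncalibrated photograph
    scale) and perturbed along local normals with sd ``noise_sd`` (mm).
    """
    from .calibration import check_phase_params, simulate_phase
    check_phase_params(phase, true_params)
    contour = simulate_phase(phase, label_map, true_params,
                             spec=spec, **simulate_kwargs)
    obs = contour / float(aspect_ratio)
    chest_x = (spec.chest_depth if spec is not None else 3.0) / aspect_ratio
    obs = perturb_contour(obs, noise_sd, rng_for(seed, "obs-noise", phase),
                          freeze_x_below=chest_x + 1.0)
    return SyntheticObservation(phase=phase, contour=obs,
                                true_params=dict(true_params),
                                noise_sd=noise_sd, aspect_ratio=aspect_ratio)


# ---------------------------------------------------------------------------
# plain-text I/O (PGM images, CSV contours)
# ---------------------------------------------------------------------------

def write_pgm(path: str | Path, image: np.ndarray, maxval: int = 255) -> None:
    """Write a 2D array as ASCII PGM (P2), row 0 at the top of the file."""
    img = np.clip(np.asarray(image), 0, maxval).astype(int)[::-1]
    lines = [f"P2\n{img.shape[1]} {img.shape[0]}\n{maxval}\n"]
    for row in img:
        lines.append(" ".join(map(str, row)) + "\n")
    Path(path).write_text("".join(lines))


def read_pgm(path: str | Path) -> np.ndarray:
    tokens = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0]
        tokens.extend(line.split())
    if tokens[0] != "P2":
        raise ValueError("only ASCII PGM (P2) supported")
    w, h = int(tokens[1]), int(tokens[2])
    data = np.array(tokens[4:4 + w * h], dtype=int).reshape(h, w)
    return data[::-1]


def write_contour_csv(path: str | Path, contour: np.ndarray) -> None:
    arr = np.asarray(contour, dtype=float)
    header = "x_mm,y_mm"
    np.savetxt(path, arr, delimiter=",", header=header, comments="")


def read_contour_csv(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", skiprows=1)
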