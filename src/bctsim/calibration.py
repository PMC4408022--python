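"""Contour-based calibration of the multifactorial BCT model.

The model is fitted to observed breast-profile contours phase by phase.
For each healing phase a small set of unknown parameters alpha is searched
on a grid; at every grid point the forward model produces a simulated
contour C_model, and the objective

    f(alpha, s) = sum_ij | C_model_ij(alpha) - s * C_gt_ij |

counts mismatched cells after both contours are rasterised onto a square
region of interest at the MRI pixel pitch.  The scalar s is a nuisance
aspect ratio absorbing the unknown photograph scale and is minimised out
per grid point.  Phases:

* Phase 0 (pre-surgery): alpha = (E_fat, E_glandular, E_skin), seated
  gravity on the intact breast.
* Phase I (inflammation, weeks 1-6): alpha = (lambda1, P); fat/glandular
  stiffness scaled by lambda1, skin unchanged, a 5 mm ring of 80 kPa
  inflamed tissue around the cavity, seroma pressure P on the cavity wall.
* Phase II (healing, weeks 7-20): alpha = (lambda2, alpha0); the coupled
  mecano-biological model heals the wound for 19 weeks, pressure returns
  to zero, stiffness scaled by lambda2.
* Phase III (radiotherapy, weeks 21-35): alpha = (lambda3, E_scar); the
  wound is closed and filled with scar tissue of unknown modulus, fat and
  glandular stiffness scaled by lambda3.
"""

from __future__ import annotations

import itertools
import warnings
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .phantom import (MRI_PITCH, PhantomSpec, SyntheticObservation,
                      TissueLabelMap, generate_phantom, rng_for)
from .mesh import (CavitySpec, apply_virtual_lumpectomy, build_mesh,
                   mark_inflamed_ring, remesh_from_wound, SCAR)
from .mechanics import (GRAVITY_SEATED, LoadCase, Material, material_table,
                        outer_contour, solve_equilibrium)

__all__ = ["PHASE_BOUNDS", "FixedParams", "RasterContour", "PhaseFit",
           "check_phase_params", "rasterize", "objective_f", "minimize_s",
           "simulate_phase", "fit_phase", "default_grids", "run_full_study",
           "plot_surface"]

#: Calibration search bounds per phase (the bold rows of the parameter
#: table: moduli in kPa, P in Pa, the lambdas and alpha0 dimensionless).
PHASE_BOUNDS = {
    "0": {"E_fat": (2.0, 15.0), "E_glandular": (5.0, 15.0),
          "E_skin": (5.0, 30.0)},
    "I": {"lambda1": (1.0, 3.0), "P": (0.0, 500.0)},
    "II": {"lambda2": (1.0, 3.0), "alpha0": (0.0, 0.6)},
    "III": {"lambda3": (1.0, 3.0), "E_scar": (10.0, 80.0)},
}


def check_phase_params(phase: str, params: dict) -> None:
    if phase not in PHASE_BOUNDS:
        raise ValueError(f"unknown phase {phase!r}")
    bounds = PHASE_BOUNDS[phase]
    for name, (lo, hi) in bounds.items():
        if name not in params:
            raise ValueError(f"phase {phase} needs parameter {name!r}")
        v = params[name]
        if not (lo - 1e-9 <= v <= hi + 1e-9):
            raise ValueError(f"{name}={v} outside bounds [{lo}, {hi}]")
    extra = set(params) - set(bounds)
    if extra:
        raise ValueError(f"unexpected parameters for phase {phase}: {extra}")


@dataclass
class FixedParams:
    """Literature-fixed model parameters threaded through all phases."""

    nu: float = 0.49
    rho_fat: float = 0.9              # kg/L
    rho_glandular: float = 1.0
    rho_skin: float = 1.0
    E_inflammation: float = 80.0      # kPa
    delta_inflammation: float = 5.0   # mm ring around the cavity
    cavity_margin: float = 5.0        # mm surgical negative margin
    phase2_weeks: int = 19
    lattice_spacing: float = 1.0      # mm, CA lattice
    mesh_size: float = 3.0            # mm, FE target element size
    healing_seed: int = 0
    D: float = 0.05                   # cm^2/day
    Lambda: float = 0.0
    alpha1: float = 0.0


@dataclass
class RasterContour:
    """Indicator grid of cells crossed by a contour in a square ROI."""

    grid: np.ndarray                  # (ny, nx) bool
    origin: tuple[float, float]       # mm
    resolution: float                 # mm per cell

    @property
    def count(self) -> int:
        return int(np.count_nonzero(self.grid))


def _densify(contour: np.ndarray, step: float) -> np.ndarray:
    pts = np.asarray(contour, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    segs = np.diff(closed, axis=0)
    out = []
    for p, d in zip(closed[:-1], segs):
        n = max(1, int(np.ceil(np.hypot(*d) / step)))
        t = np.arange(n) / n
        out.append(p + t[:, None] * d)
    return np.vstack(out)


def rasterize(contour: np.ndarray, roi: tuple[float, float, float] | None,
              resolution: float = MRI_PITCH) -> RasterContour:
    """Mark the ROI cells crossed by a closed polyline.

    ``roi = (x0, y0, size)`` in mm; None picks the bounding square of the
    contour with one cell of padding.  Raises if the contour is empty or
    leaves an explicit ROI.
    """
    pts = np.asarray(contour, dtype=float)
    if pts.size == 0:
        raise ValueError("empty contour")
    dense = _densify(pts, resolution / 4.0)
    if roi is None:
        # half-cell offset keeps coordinates off exact cell boundaries
        x0 = dense[:, 0].min() - 0.5 * resolution
        y0 = dense[:, 1].min() - 0.5 * resolution
        size = max(dense[:, 0].max() - x0, dense[:, 1].max() - y0) \
            + resolution
    else:
        x0, y0, size = roi
    n = int(np.ceil(size / resolution))
    ix = np.floor((dense[:, 0] - x0) / resolution).astype(int)
    iy = np.floor((dense[:, 1] - y0) / resolution).astype(int)
    if roi is not None and ((ix < 0) | (ix >= n) | (iy < 0) | (iy >= n)).any():
        raise ValueError("contour outside the ROI")
    grid = np.zeros((n, n), dtype=bool)
    grid[np.clip(iy, 0, n - 1), np.clip(ix, 0, n - 1)] = True
    return RasterContour(grid=grid, origin=(x0, y0), resolution=resolution)


def objective_f(model_contour: np.ndarray, gt_contour: np.ndarray,
                s: float = 1.0, resolution: float = MRI_PITCH,
                roi: tuple[float, float, float] | None = None) -> float:
    """Mismatched-cell count between model contour and scaled ground truth.

    Both contours are rasterised on a common square ROI (auto: bounding
    square of the union); the per-cell norm is the absolute difference of
    the indicators, so f counts cells crossed by exactly one contour and
    is zero iff the rasters coincide at scale s.
    """
    if s <= 0:
        raise ValueError("scale s must be positive")
    gt = np.asarray(gt_contour, dtype=float) * s
    model = np.asarray(model_contour, dtype=float)
    if roi is None:
        allpts = np.vstack([model, gt])
        x0 = allpts[:, 0].min() - 0.5 * resolution
        y0 = allpts[:, 1].min() - 0.5 * resolution
        size = max(allpts[:, 0].max() - x0, allpts[:, 1].max() - y0) \
            + resolution
        roi = (x0, y0, size)
    a = rasterize(model, roi, resolution)
    b = rasterize(gt, roi, resolution)
    return float(np.count_nonzero(a.grid ^ b.grid))


def _bbox_diag(pts: np.ndarray) -> float:
    span = pts.max(axis=0) - pts.min(axis=0)
    return float(np.hypot(*span))


def minimize_s(model_contour: np.ndarray, gt_contour: np.ndarray,
               s_range: tuple[float, float] = (0.5, 2.0),
               resolution: float = MRI_PITCH) -> tuple[float, float]:
    """Best aspect ratio s and the corresponding objective value.

    f is piecewise constant in s, so the search combines a coarse global
    scan over ``s_range``, a fine scan around the bounding-box size ratio
    (which is exact for a purely rescaled contour), and a final local
    refinement around the best candidate.
    """
    model = np.asarray(model_contour, dtype=float)
    gt = np.asarray(gt_contour, dtype=float)
    lo, hi = s_range

    def f(s):
        return objective_f(model, gt, s, resolution)

    cands = list(np.linspace(lo, hi, 16))
    s0 = _bbox_diag(model) / max(_bbox_diag(gt), 1e-12)
    if lo <= s0 <= hi:
        cands += list(s0 * np.linspace(0.98, 1.02, 41))
    cands = [s for s in cands if lo <= s <= hi]
    vals = [f(s) for s in cands]
    best = int(np.argmin(vals))
    s_best, f_best = cands[best], vals[best]
    # local refinement around the winner
    width = (hi - lo) / 15.0
    for s in np.linspace(max(lo, s_best - width), min(hi, s_best + width), 41):
        v = f(s)
        if v < f_best:
            s_best, f_best = float(s), v
    return float(s_best), float(f_best)


# ---------------------------------------------------------------------------
# phase forward models
# ---------------------------------------------------------------------------

def _cavity_spec(spec: PhantomSpec, fixed: FixedParams) -> CavitySpec:
    return CavitySpec(center=spec.tumor_centre(), bed_axes=spec.tumor_axes,
                      margin=fixed.cavity_margin)


def _materials(fixed: FixedParams, E_fat, E_glandular, E_skin,
               E_scar=None) -> dict[int, Material]:
    return material_table(E_fat, E_glandular, E_skin, E_scar=E_scar,
                          E_inflamed=fixed.E_inflammation, nu=fixed.nu,
                          rho_fat=fixed.rho_fat,
                          rho_glandular=fixed.rho_glandular,
                          rho_skin=fixed.rho_skin)


def _phase2_mesh(label_map, spec, fixed, alpha0, prior, cache):
    """Week-19 healed mesh for a given alpha0 (cached across the grid)."""
    key = ("phase2", round(float(alpha0), 10))
    if cache is not None and key in cache:
        return cache[key]
    from .healing import HealingParams, coupling_loop
    mesh0 = build_mesh(label_map, fixed.mesh_size)
    mesh_cav = apply_virtual_lumpectomy(mesh0, _cavity_spec(spec, fixed))
    params = HealingParams(D=fixed.D, Lambda=fixed.Lambda, alpha0=alpha0,
                           alpha1=fixed.alpha1)
    mats = _materials(fixed, prior["E_fat"], prior["E_glandular"],
                      prior["E_skin"], E_scar=prior["E_glandular"])
    records = coupling_loop(mesh_cav, mats, params,
                            total_weeks=fixed.phase2_weeks,
                            seed=fixed.healing_seed,
                            spacing=fixed.lattice_spacing)
    mesh19 = records[-1].mesh
    if cache is not None:
        cache[key] = (mesh19, records)
    return mesh19, records


def simulate_phase(phase: str, label_map: TissueLabelMap | None,
                   params: dict, spec: PhantomSpec | None = None,
                   fixed: FixedParams | None = None,
                   prior: dict | None = None,
                   cache: dict | None = None,
                   pressure_override: float | None = None) -> np.ndarray:
    """Predicted seated breast contour for one phase at parameters alpha.

    ``prior`` carries the Phase-0 baseline moduli (keys E_fat,
    E_glandular, E_skin) required by phases I-III; ``cache`` (a plain
    dict) reuses healed meshes and warm-starts across repeated calls, as
    in a grid search.
    """
    check_phase_params(phase, params)
    fixed = fixed or FixedParams()
    spec = spec or PhantomSpec()
    if label_map is None:
        label_map = generate_phantom(spec)
    contour_key = ("contour", phase, tuple(sorted(params.items())))
    if cache is not None and contour_key in cache:
        return cache[contour_key]
    if phase != "0":
        if prior is None:
            raise ValueError(f"phase {phase} requires the Phase-0 baseline "
                             "moduli as `prior`")
        E0 = (prior["E_fat"], prior["E_glandular"], prior["E_skin"])
    cache = cache if cache is not None else {}
    load = LoadCase(gravity=GRAVITY_SEATED)

    if phase == "0":
        if "mesh0" not in cache:
            cache["mesh0"] = build_mesh(label_map, fixed.mesh_size)
        mesh = cache["mesh0"]
        mats = _materials(fixed, params["E_fat"], params["E_glandular"],
                          params["E_skin"])
    elif phase == "I":
        if "meshI" not in cache:
            mesh0 = build_mesh(label_map, fixed.mesh_size)
            mesh_cav = apply_virtual_lumpectomy(mesh0,
                                                _cavity_spec(spec, fixed))
            cache["meshI"] = mark_inflamed_ring(mesh_cav,
                                                fixed.delta_inflammation)
        mesh = cache["meshI"]
        lam = params["lambda1"]
        mats = _materials(fixed, lam * E0[0], lam * E0[1], E0[2])
        P = params["P"] if pressure_override is None else pressure_override
        load = LoadCase(gravity=GRAVITY_SEATED, pressure=P)
    elif phase == "II":
        mesh, _ = _phase2_mesh(label_map, spec, fixed, params["alpha0"],
                               prior, cache)
        lam = params["lambda2"]
        mats = _materials(fixed, lam * E0[0], lam * E0[1], E0[2],
                          E_scar=lam * E0[1])
    else:                              # Phase III
        if "meshIII" not in cache:
            mesh0 = build_mesh(label_map, fixed.mesh_size)
            mesh_cav = apply_virtual_lumpectomy(mesh0,
                                                _cavity_spec(spec, fixed))
            cache["meshIII"] = remesh_from_wound(mesh_cav, None)
        mesh = cache["meshIII"]
        lam = params["lambda3"]
        mats = _materials(fixed, lam * E0[0], lam * E0[1], E0[2],
                          E_scar=params["E_scar"])

    warm_key = ("warm", phase, params.get("alpha0"))
    u0 = cache.get(warm_key)
    state = solve_equilibrium(mesh, mats, load, u0=u0)
    cache[warm_key] = state.u
    cache[("laststate", phase)] = state
    contour = outer_contour(state)
    cache[contour_key] = contour
    return contour


# ---------------------------------------------------------------------------
# grid-search calibration
# ---------------------------------------------------------------------------

#: Default search grids: uniform, inside the calibration bounds, with the
#: study's fitted values on interior grid points.  "full" mirrors the
#: published surface-response granularity; "reduced" is a coarser
#: screening grid for quick runs.
_GRIDS = {
    ("0", "full"): {"E_fat": np.arange(2.0, 15.01, 0.85),
                    "E_glandular": np.arange(5.0, 15.01, 1.5),
                    "E_skin": np.arange(5.0, 30.01, 5.0)},
    ("0", "reduced"): {"E_fat": np.arange(2.0, 15.01, 1.7),
                       "E_glandular": np.arange(6.5, 12.51, 1.5),
                       "E_skin": np.arange(15.0, 30.01, 5.0)},
    ("I", "full"): {"lambda1": np.linspace(1.0, 3.0, 11),
                    "P": np.linspace(0.0, 400.0, 11)},
    ("I", "reduced"): {"lambda1": np.arange(1.0, 3.01, 0.5),
                       "P": np.arange(0.0, 361.0, 60.0)},
    ("II", "full"): {"lambda2": np.linspace(1.0, 3.0, 11),
                     "alpha0": 0.0425 * np.arange(15)},
    ("II", "reduced"): {"lambda2": np.arange(1.0, 3.01, 0.2),
                        "alpha0": 0.085 * np.arange(8)},
    ("III", "full"): {"lambda3": np.linspace(1.2, 2.2, 11),
                      "E_scar": np.arange(10.0, 80.01, 7.0)},
    ("III", "reduced"): {"lambda3": np.arange(1.2, 2.21, 0.25),
                         "E_scar": np.arange(10.0, 80.01, 14.0)},
}


def default_grids(phase: str, level: str = "reduced") -> dict[str, np.ndarray]:
    return {k: v.copy() for k, v in _GRIDS[(phase, level)].items()}


@dataclass
class PhaseFit:
    """Result of one phase's grid search."""

    phase: str
    axes: dict                        # name -> grid array (search order)
    f: np.ndarray                     # objective, shape = grid shape
    s_opt: np.ndarray                 # minimising aspect ratio per point
    argmin: dict                      # name -> fitted value
    s_hat: float
    f_min: float

    def range_along(self, name: str) -> float:
        """Objective range along one axis through the argmin (sensitivity)."""
        names = list(self.axes)
        idx = [int(np.argmin(np.abs(self.axes[n] - self.argmin[n])))
               for n in names]
        ax = names.index(name)
        sl = list(idx)
        sl[ax] = slice(None)
        line = self.f[tuple(sl)]
        return float(line.max() - line.min())


def fit_phase(phase: str, observation: SyntheticObservation | np.ndarray,
              grids: dict[str, np.ndarray] | None = None,
              label_map: TissueLabelMap | None = None,
              spec: PhantomSpec | None = None,
              fixed: FixedParams | None = None,
              prior: dict | None = None,
              resolution: float = MRI_PITCH,
              s_range: tuple[float, float] = (0.5, 2.0),
              cache: dict | None = None) -> PhaseFit:
    """Exhaustive surface-response calibration of one phase.

    Evaluates f (minimised over the aspect ratio s) at every point of the
    parameter grid and returns the full objective surface with its argmin.
    Grid axes are ordered so that mesh-changing parameters (alpha0 in
    Phase II) vary slowest, letting healed meshes and solver warm starts
    be reused.
    """
    if grids is None:
        grids = default_grids(phase)
    names = list(grids)
    if phase == "II" and "alpha0" in names:
        names = ["alpha0"] + [n for n in names if n != "alpha0"]
    axes = {n: np.asarray(grids[n], dtype=float) for n in names}
    for n in names:
        lo, hi = PHASE_BOUNDS[phase][n]
        if axes[n].min() < lo - 1e-9 or axes[n].max() > hi + 1e-9:
            raise ValueError(f"grid for {n} outside bounds [{lo}, {hi}]")
    gt = observation.contour if isinstance(observation, SyntheticObservation) \
        else np.asarray(observation, dtype=float)

    shape = tuple(len(axes[n]) for n in names)
    fvals = np.full(shape, np.inf)
    svals = np.ones(shape)
    cache = cache if cache is not None else {}
    n_fail = 0
    for idx in itertools.product(*(range(k) for k in shape)):
        params = {n: float(axes[n][i]) for n, i in zip(names, idx)}
        try:
            contour = simulate_phase(phase, label_map, params, spec=spec,
                                     fixed=fixed, prior=prior, cache=cache)
        except Exception as err:
            warnings.warn(f"phase {phase} forward model failed at "
                          f"{params}: {err}")
            n_fail += 1
            continue
        s, fv = minimize_s(contour, gt, s_range, resolution)
        fvals[idx] = fv
        svals[idx] = s
    if not np.isfinite(fvals).any():
        raise RuntimeError(f"all {n_fail} forward simulations failed for "
                           f"phase {phase}")
    best = np.unravel_index(int(np.argmin(fvals)), shape)
    argmin = {n: float(axes[n][i]) for n, i in zip(names, best)}
    return PhaseFit(phase=phase, axes=axes, f=fvals, s_opt=svals,
                    argmin=argmin, s_hat=float(svals[best]),
                    f_min=float(fvals[best]))


# ---------------------------------------------------------------------------
# end-to-end study
# ---------------------------------------------------------------------------

def plot_surface(fit: PhaseFit, path) -> None:
    """Surface response of f for a two-parameter phase fit, as PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    names = list(fit.axes)
    fig, ax = plt.subplots(figsize=(5, 4))
    if len(names) == 2:
        f = np.where(np.isfinite(fit.f), fit.f, np.nan)
        pc = ax.pcolormesh(fit.axes[names[1]], fit.axes[names[0]], f,
                           shading="nearest")
        fig.colorbar(pc, ax=ax, label="f (mismatched cells)")
        ax.plot(fit.argmin[names[1]], fit.argmin[names[0]], "r*", ms=12)
        ax.set_xlabel(names[1])
        ax.set_ylabel(names[0])
    else:
        for n in names:
            ax.plot(fit.axes[n], [fit.range_along(n)] * len(fit.axes[n]),
                    label=n)
        ax.set_ylabel("objective range along axis")
        ax.legend()
    ax.set_title(f"Phase {fit.phase} surface response")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


#: The study's published best-fit parameters, used as the default planted
#: truths for synthetic observations.
DEFAULT_TRUTHS = {
    "0": {"E_fat": 3.7, "E_glandular": 9.5, "E_skin": 25.0},
    "I": {"lambda1": 2.0, "P": 120.0},
    "II": {"lambda2": 1.2, "alpha0": 0.17},
    "III": {"lambda3": 1.7, "E_scar": 24.0},
}

_PHASE_ORDER = ["0", "I", "II", "III"]


def run_full_study(config: dict | None = None, outdir: str | Path | None = None
                   ) -> dict:
    """Run the four-phase calibration study on a synthetic phantom.

    Generates the phantom and per-phase observations at the configured
    true parameters, fits Phase 0 first, threads the fitted baseline
    moduli into Phases I-III, and reports fitted parameters, objective
    minima, cosmesis metrics and the week-19 cavity size.  Reruns with the
    same master seed are byte-identical.
    """
    from .phantom import generate_observation
    from . import metrics as cm

    cfg = dict(config or {})
    phases = cfg.get("phases", _PHASE_ORDER)
    if phases != _PHASE_ORDER[:len(phases)]:
        raise ValueError("phases must run in order 0, I, II, III "
                         "(later phases need earlier fits)")
    seed = int(cfg.get("seed", 0))
    level = cfg.get("grid_level", "reduced")
    noise_sd = float(cfg.get("noise_sd", 0.0))
    aspect = float(cfg.get("aspect_ratio", 1.0))
    truths = {**DEFAULT_TRUTHS, **cfg.get("truths", {})}
    spec = cfg.get("spec") or PhantomSpec(rng_seed=seed)
    fixed = cfg.get("fixed") or FixedParams(healing_seed=seed)
    grids = cfg.get("grids", {})

    label_map = generate_phantom(spec)
    true_prior = truths["0"]
    report: dict = {"seed": seed, "grid_level": level, "phases": {}}
    fits: dict[str, PhaseFit] = {}
    contours: dict[str, np.ndarray] = {}
    shared_cache: dict = {}
    prior = None
    for phase in phases:
        obs = generate_observation(label_map, phase, truths[phase],
                                   noise_sd=noise_sd, aspect_ratio=aspect,
                                   seed=seed, spec=spec, fixed=fixed,
                                   prior=None if phase == "0" else true_prior,
                                   cache=shared_cache)
        contours[phase] = obs.contour * aspect
        fit = fit_phase(phase, obs, grids.get(phase) or default_grids(phase, level),
                        label_map=label_map, spec=spec, fixed=fixed,
                        prior=prior)
        fits[phase] = fit
        if phase == "0":
            prior = dict(fit.argmin)
        report["phases"][phase] = {
            "truth": truths[phase], "fitted": fit.argmin,
            "f_min": fit.f_min, "s_hat": fit.s_hat,
            "grid_shape": list(fit.f.shape),
            "sensitivity_range": {n: fit.range_along(n) for n in fit.axes},
        }

    # cosmesis metrics: Phase 0 contour is the "control" breast
    if "0" in contours and "I" in contours:
        report["metrics"] = {
            "nipple_height_difference_mm": cm.nipple_height_difference(
                contours["I"], contours["0"]),
            "lateral_disc_area_change_cm2": cm.lateral_disc_area(
                contours["I"]) - cm.lateral_disc_area(contours["0"]),
        }
    if "II" in fits:
        cache = {}
        _ = simulate_phase("II", label_map, fits["II"].argmin, spec=spec,
                           fixed=fixed, prior=prior, cache=cache)
        state = cache[("laststate", "II")]
        dims = cm.cavity_dimensions(state)
        report["metrics_phase2_cavity_mm"] = {
            "major": dims.major, "minor": dims.minor, "closed": dims.closed}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
        for phase, fit in fits.items():
            if len(fit.axes) == 2:
                plot_surface(fit, outdir / f"surface_phase{phase}.png")
        for phase, fit in fits.items():
            names = list(fit.axes)
            with open(outdir / f"surface_phase{phase}.csv", "w") as fh:
                fh.write(",".join(names) + ",f,s\n")
                for idx in itertools.product(
                        *(range(len(fit.axes[n])) for n in names)):
                    row = [f"{fit.axes[n][i]:.6g}"
                           for n, i in zip(names, idx)]
                    fh.write(",".join(row) + f",{fit.f[idx]:.6g},"
                             f"{fit.s_opt[idx]:.6g}\n")
    report["_fits"] = fits
    report["_contours"] = contours
    return report
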