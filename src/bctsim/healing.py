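"""Mecano-biological wound-healing model.

The lumpectomy wound heals by cell division on a hexagonal cellular
automaton (CA) living on the *unloaded* breast geometry, fed by a generic
growth factor c that diffuses through the surrounding tissue:

    dc/dt - D lap(c) + Lambda c = chi_al,

where the unit source chi_al acts in an "active layer" of tissue rings
hugging the wound edge, with no-flux conditions at the wound wall and a
homogeneous Dirichlet far field.  Each day, an empty wound-edge site is
colonised with probability

    p = F(c) * (alpha0 + alpha1 * E_hat),

F a hard cut-off on the local growth-factor level and E_hat the normalised
mechanical stimulus mapped from the loaded configuration.  Weekly, the
breast mesh is rebuilt around the shrunken wound and the mechanics is
re-solved (the mechanics feedback only matters when alpha1 > 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import sparse
from scipy.sparse.linalg import spsolve
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .mesh import BreastMesh, remesh_from_wound
from .phantom import FAT, GLANDULAR, SKIN, rng_for

__all__ = ["HealingParams", "HealingState", "WeekRecord", "init_healing",
           "solve_growth_factor", "division_probability", "step_ca",
           "active_layer", "wound_polygon", "level_set_reference",
           "coupling_loop", "site_area", "write_trajectory_csv",
           "write_lattice_csv"]

_NEIGHBOR_OFFSETS = np.array([(1, 0), (-1, 0), (0, 1), (0, -1),
                              (1, -1), (-1, 1)])


@dataclass
class HealingParams:
    """Biological parameters of the healing model.

    Defaults follow the study's biological table: D = 0.05 cm^2/day,
    Lambda = 0, alpha1 = 0 (no mechanical feedback), unit source in the
    active layer.  ``c_threshold = None`` resolves, at evaluation time, to
    10% of the mean steady growth-factor level in the active layer.
    """

    D: float = 0.05                  # diffusion, cm^2/day
    Lambda: float = 0.0              # decay, 1/day
    alpha0: float = 0.17             # baseline division probability in [0, 0.6]
    alpha1: float = 0.0              # stress sensitivity
    active_rings: int = 2            # active-layer width in lattice rings
    chi: float = 1.0                 # source amplitude in the active layer
    c_threshold: float | None = None
    ca_step_days: float = 7.0       # one division sweep per coupling interval
    coupling_interval_days: float = 7.0
    far_field: str = "dirichlet"     # "dirichlet" (c=0 rim) or "neumann"
    far_field_pad: float = 15.0      # mm of tissue kept around the cavity

    def __post_init__(self):
        if self.D <= 0 or self.Lambda < 0:
            raise ValueError("need D > 0 and Lambda >= 0")
        if self.alpha0 < 0 or self.alpha1 < 0:
            raise ValueError("alpha0, alpha1 must be >= 0")
        if self.active_rings < 1:
            raise ValueError("active layer needs at least one ring")

    @property
    def D_mm2(self) -> float:
        return self.D * 100.0        # cm^2/day -> mm^2/day


@dataclass
class HealingState:
    """Hexagonal-lattice occupancy + growth factor around the wound."""

    qr: np.ndarray                   # (S, 2) axial coordinates
    xy: np.ndarray                   # (S, 2) site centers, mm
    neighbors: np.ndarray            # (S, 6), -1 where absent
    occupied: np.ndarray             # (S,) bool; False = wound
    c: np.ndarray                    # (S,) growth factor
    spacing: float                   # mm between adjacent sites
    far_field: np.ndarray            # (S,) bool, Dirichlet rim sites
    elapsed_days: float = 0.0

    def wound_sites(self) -> np.ndarray:
        return np.nonzero(~self.occupied)[0]

    def wound_edge(self) -> np.ndarray:
        """Empty sites adjacent to at least one occupied site."""
        occ_nb = self._neighbor_any(self.occupied)
        return np.nonzero(~self.occupied & occ_nb)[0]

    def wound_area(self) -> float:
        return float(np.count_nonzero(~self.occupied)) * site_area(self.spacing)

    def _neighbor_any(self, mask: np.ndarray) -> np.ndarray:
        padded = np.concatenate([mask, [False]])
        return padded[self.neighbors].any(axis=1)

    def copy(self) -> "HealingState":
        return HealingState(self.qr, self.xy, self.neighbors,
                            self.occupied.copy(), self.c.copy(),
                            self.spacing, self.far_field, self.elapsed_days)


def site_area(spacing: float) -> float:
    """Area of one hexagonal lattice cell (mm^2)."""
    return np.sqrt(3.0) / 2.0 * spacing ** 2


def _axial_xy(qr: np.ndarray, s: float) -> np.ndarray:
    x = s * (qr[:, 0] + qr[:, 1] / 2.0)
    y = s * (np.sqrt(3.0) / 2.0) * qr[:, 1]
    return np.column_stack([x, y])


def _build_lattice(bounds: tuple[float, float, float, float], s: float):
    """Axial hex lattice covering a rectangle; returns qr, xy, neighbors."""
    x0, y0, x1, y1 = bounds
    r0 = int(np.floor(y0 / (s * np.sqrt(3) / 2)))
    r1 = int(np.ceil(y1 / (s * np.sqrt(3) / 2)))
    qr = []
    for r in range(r0, r1 + 1):
        q0 = int(np.floor(x0 / s - r / 2.0))
        q1 = int(np.ceil(x1 / s - r / 2.0))
        qr.extend((q, r) for q in range(q0, q1 + 1))
    qr = np.array(qr, dtype=int)
    return qr


def _neighbor_table(qr: np.ndarray) -> np.ndarray:
    index = {(int(q), int(r)): i for i, (q, r) in enumerate(qr)}
    nb = np.full((len(qr), 6), -1, dtype=int)
    for i, (q, r) in enumerate(qr):
        for k, (dq, dr) in enumerate(_NEIGHBOR_OFFSETS):
            j = index.get((int(q) + dq, int(r) + dr))
            if j is not None:
                nb[i, k] = j
    return nb


def init_healing(mesh: BreastMesh, spacing: float,
                 params: HealingParams) -> HealingState:
    """Lay a hexagonal lattice over the cavity neighbourhood of an
    (unloaded) mesh: sites inside the cavity are empty, tissue sites are
    occupied, the lattice rim is the Dirichlet far field, c starts at 0."""
    if mesh.cavity is None or mesh.cavity.is_empty:
        cavity = None
    else:
        cavity = mesh.cavity
    if cavity is not None:
        minx, miny, maxx, maxy = cavity.bounds
        minor = min(maxx - minx, maxy - miny) / 2.0
        if spacing > minor / 4.0:
            raise ValueError(f"lattice spacing {spacing} too coarse for "
                             f"cavity minor radius {minor:.1f}")
        pad = params.far_field_pad
        bounds = (minx - pad, miny - pad, maxx + pad, maxy + pad)
    else:
        minx, miny = mesh.nodes.min(axis=0)
        maxx, maxy = mesh.nodes.max(axis=0)
        bounds = (minx, miny, maxx, maxy)

    qr = _build_lattice(bounds, spacing)
    xy = _axial_xy(qr, spacing)
    # keep only sites inside breast tissue or inside the cavity
    if mesh.label_map is not None:
        lab = mesh.label_map.label_at(xy[:, 0], xy[:, 1])
        keep = np.isin(lab, (FAT, GLANDULAR, SKIN))
    else:
        keep = np.ones(len(qr), dtype=bool)
    if cavity is not None:
        keep |= shapely.contains(cavity, shapely.points(xy))
    qr, xy = qr[keep], xy[keep]
    nb = _neighbor_table(qr)

    occupied = np.ones(len(qr), dtype=bool)
    if cavity is not None:
        occupied[shapely.contains(cavity, shapely.points(xy))] = False
    far = (nb < 0).any(axis=1) & occupied
    return HealingState(qr=qr, xy=xy, neighbors=nb, occupied=occupied,
                        c=np.zeros(len(qr)), spacing=spacing, far_field=far)


def active_layer(state: HealingState, n_rings: int) -> np.ndarray:
    """Occupied sites within ``n_rings`` lattice rings of the wound edge."""
    if not (~state.occupied).any():
        return np.zeros(len(state.qr), dtype=bool)
    frontier = ~state.occupied
    layer = np.zeros(len(state.qr), dtype=bool)
    visited = frontier.copy()
    for _ in range(n_rings):
        padded = np.concatenate([frontier, [False]])
        nxt = padded[state.neighbors].any(axis=1) & state.occupied & ~visited
        layer |= nxt
        visited |= nxt
        frontier = nxt
        if not frontier.any():
            break
    return layer


def _hex_laplacian(state: HealingState) -> sparse.csr_matrix:
    """Graph Laplacian approximating the continuum Laplacian on the
    occupied sublattice; missing/empty neighbours give natural no-flux."""
    s2 = state.spacing ** 2
    w = 2.0 / (3.0 * s2)
    occ = state.occupied
    idx = np.nonzero(occ)[0]
    pos = -np.ones(len(state.qr), dtype=int)
    pos[idx] = np.arange(len(idx))
    rows, cols, vals = [], [], []
    for k in range(6):
        nbk = state.neighbors[idx, k]
        good = (nbk >= 0) & occ[np.clip(nbk, 0, None)]
        i = pos[idx[good]]
        j = pos[nbk[good]]
        rows.extend([i, i])
        cols.extend([j, i])
        vals.extend([np.full(len(i), w), np.full(len(i), -w)])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    n = len(idx)
    return sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr(), idx


def solve_growth_factor(state: HealingState, params: HealingParams,
                        duration: float | None = None,
                        dt: float = 1.0,
                        source: np.ndarray | None = None) -> np.ndarray:
    """Growth-factor field on the occupied sites.

    ``duration=None`` solves the steady problem -D lap c + Lambda c = chi
    directly (requires decay or a Dirichlet far field); otherwise implicit
    Euler steps of ``dt`` days integrate to ``duration``.  Updates and
    returns ``state.c``.
    """
    L, idx = _hex_laplacian(state)
    n = L.shape[0]
    if source is None:
        chi = np.where(active_layer(state, params.active_rings)[idx],
                       params.chi, 0.0)
    else:
        chi = np.asarray(source, dtype=float)[idx]
    dirichlet = (state.far_field[idx]
                 if params.far_field == "dirichlet"
                 else np.zeros(n, dtype=bool))

    A_steady = (-params.D_mm2 * L
                + params.Lambda * sparse.eye(n, format="csr"))

    def apply_bc(A, b):
        if dirichlet.any():
            A = A.tolil()
            for i in np.nonzero(dirichlet)[0]:
                A.rows[i], A.data[i] = [i], [1.0]
            A = A.tocsr()
            b = b.copy()
            b[dirichlet] = 0.0
        return A, b

    if duration is None:
        if params.Lambda <= 0 and not dirichlet.any():
            raise ValueError("steady state undefined: no decay and no "
                             "Dirichlet far field")
        A, b = apply_bc(A_steady, chi)
        cv = spsolve(A.tocsc(), b)
    else:
        cv = state.c[idx].copy()
        nsteps = max(1, int(round(duration / dt)))
        dt_eff = duration / nsteps
        A = sparse.eye(n, format="csr") / dt_eff + A_steady
        A, _ = apply_bc(A, chi)
        A = A.tocsc()
        lu = sparse.linalg.splu(A)
        for _ in range(nsteps):
            b = cv / dt_eff + chi
            if dirichlet.any():
                b[dirichlet] = 0.0
            cv = lu.solve(b)
    cv = np.maximum(cv, 0.0)
    state.c[:] = 0.0
    state.c[idx] = cv
    return state.c


def _resolve_threshold(state: HealingState, params: HealingParams) -> float:
    if params.c_threshold is not None:
        return params.c_threshold
    act = active_layer(state, params.active_rings)
    if not act.any():
        return 0.0
    return 0.1 * float(state.c[act].mean())


def division_probability(state: HealingState, params: HealingParams,
                         E_hat: np.ndarray | None = None) -> np.ndarray:
    """Daily division probability per occupied site: F(c)(a0 + a1 E_hat)."""
    c = state.c
    thr = _resolve_threshold(state, params)
    F = (c >= thr).astype(float)
    e = np.zeros(len(c)) if E_hat is None else np.clip(E_hat, 0.0, 1.0)
    p = F * (params.alpha0 + params.alpha1 * e)
    p[~state.occupied] = 0.0
    return np.clip(p, 0.0, 1.0)


def step_ca(state: HealingState, p: np.ndarray,
            rng: np.random.Generator) -> HealingState:
    """One CA day: wound-edge sites are colonised by dividing neighbours.

    Each empty wound-edge site is filled with the division probability of
    its adjacent occupied active-layer tissue (the strongest candidate
    parent); all decisions use the pre-step state, so the update is
    simultaneous and bit-reproducible for a fixed generator state.  Wound
    area never increases.
    """
    new = state.copy()
    act = active_layer(state, n_rings=1)    # parents must touch the edge
    eligible_parent = state.occupied & act & (p > 0)
    edge = state.wound_edge()
    if len(edge) == 0:
        new.elapsed_days += 1.0
        return new
    p_pad = np.concatenate([np.where(eligible_parent, p, 0.0), [0.0]])
    p_edge = p_pad[state.neighbors[edge]].max(axis=1)
    fill = rng.random(len(edge)) < p_edge
    new.occupied[edge[fill]] = True
    new.c[edge[fill]] = 0.0
    new.elapsed_days += 1.0
    return new


def wound_polygon(state: HealingState) -> Polygon | None:
    """Union of the hexagonal cells of the empty sites (None when closed)."""
    empty = state.wound_sites()
    if len(empty) == 0:
        return None
    s = state.spacing
    rad = s / np.sqrt(3.0)
    ang = np.radians(30 + 60 * np.arange(6))
    hex_dx = rad * np.cos(ang)
    hex_dy = rad * np.sin(ang)
    cells = [Polygon(np.column_stack([state.xy[i, 0] + hex_dx,
                                      state.xy[i, 1] + hex_dy]))
             for i in empty]
    poly = unary_union(cells).buffer(1e-9)
    if poly.geom_type == "MultiPolygon":
        poly = max(poly.geoms, key=lambda g: g.area)
    return Polygon(poly.exterior).simplify(0.2 * s)


def level_set_reference(polygon: Polygon | np.ndarray, speed: float,
                        duration: float, dt: float = 1.0) -> Polygon:
    """Sharp-interface oracle: inward normal front propagation at constant
    speed (mm/day), realised by iterated negative buffering.  Used only as
    a cross-check of the CA; returns an empty polygon on collapse."""
    poly = polygon if isinstance(polygon, Polygon) else Polygon(np.asarray(polygon))
    t = 0.0
    while t < duration - 1e-12 and not poly.is_empty:
        step = min(dt, duration - t)
        poly = poly.buffer(-speed * step)
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
        t += step
    return poly


def write_trajectory_csv(records: list["WeekRecord"], path) -> None:
    """Healing trajectory as CSV (week, wound area and principal axes)."""
    import pandas as pd
    from .metrics import cavity_dimensions
    rows = []
    for r in records:
        dims = cavity_dimensions(r.wound_poly) if r.wound_poly is not None \
            else cavity_dimensions(np.empty((0, 2)))
        rows.append({"week": r.week, "wound_area_mm2": r.wound_area_mm2,
                     "wound_major_mm": dims.major,
                     "wound_minor_mm": dims.minor})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_lattice_csv(state: HealingState, path) -> None:
    """Lattice state as CSV (axial coordinates, occupancy, growth factor)."""
    import pandas as pd
    pd.DataFrame({"q": state.qr[:, 0], "r": state.qr[:, 1],
                  "x_mm": state.xy[:, 0], "y_mm": state.xy[:, 1],
                  "occupied": state.occupied.astype(int),
                  "c": state.c}).to_csv(path, index=False)


@dataclass
class WeekRecord:
    week: int
    wound_area_mm2: float
    mesh: BreastMesh
    healing: HealingState
    mech_state: object = None
    wound_poly: Polygon | None = None


def coupling_loop(mesh: BreastMesh, materials, params: HealingParams,
                  total_weeks: int, seed: int = 0, spacing: float = 1.0,
                  load=None, record_mechanics: bool = False,
                  lattice: HealingState | None = None) -> list[WeekRecord]:
    """Weekly alternation of breast mechanics and CA wound healing.

    Per coupling interval: solve the loaded equilibrium, normalise the
    stress field and map it onto the unloaded lattice (nearest material
    point), solve the growth-factor field, run the CA for the interval,
    then remesh the breast around the new wound boundary.  When
    ``alpha1 = 0`` and mechanics recording is off the equilibrium solve is
    skipped — the stimulus would multiply to zero.
    """
    from .mechanics import (LoadCase, normalized_stress, solve_equilibrium)
    from scipy.spatial import cKDTree

    if mesh.cavity is None:
        raise ValueError("coupling loop needs a mesh with a cavity")
    state = lattice if lattice is not None else init_healing(mesh, spacing, params)
    rng = rng_for(seed, "ca")
    load = load or LoadCase()
    records: list[WeekRecord] = []
    u_warm = None
    days_per_week = params.coupling_interval_days
    for week in range(1, total_weeks + 1):
        mech, ehat_sites = None, None
        if params.alpha1 > 0 or record_mechanics:
            mech = solve_equilibrium(mesh, materials, load, u0=u_warm)
            u_warm = None          # mesh changes weekly; restart next time
            ehat = normalized_stress(mech)
            cent = mesh.nodes[mesh.tris].mean(axis=1)
            tree = cKDTree(cent)
            _, nearest = tree.query(state.xy)
            ehat_sites = ehat[nearest]
        solve_growth_factor(state, params)
        ndays = max(1, int(round(days_per_week / params.ca_step_days)))
        for _ in range(ndays):
            p = division_probability(state, params, ehat_sites)
            state = step_ca(state, p, rng)
        poly = wound_polygon(state)
        mesh = remesh_from_wound(mesh, poly)
        records.append(WeekRecord(week=week, wound_area_mm2=state.wound_area(),
                                  mesh=mesh, healing=state.copy(),
                                  mech_state=mech, wound_poly=poly))
        if poly is None:
            break
    return records
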