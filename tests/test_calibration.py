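"""Contour objective, rasterisation, forward phases, grid-search fitting."""

import numpy as np
import pytest

from bctsim.phantom import generate_observation
from bctsim.mesh import build_mesh, apply_virtual_lumpectomy
from bctsim.mechanics import LoadCase, material_table, outer_contour, \
    solve_equilibrium
from bctsim.calibration import (FixedParams, check_phase_params, default_grids,
                                fit_phase, minimize_s, objective_f, rasterize,
                                run_full_study, simulate_phase, PHASE_BOUNDS)

RES = 0.7031


class TestParamValidation:
    def test_unknown_phase_and_bounds(self):
        with pytest.raises(ValueError):
            check_phase_params("IV", {})
        with pytest.raises(ValueError):
            check_phase_params("I", {"lambda1": 0.5, "P": 100.0})
        with pytest.raises(ValueError):
            check_phase_params("I", {"lambda1": 2.0})
        check_phase_params("I", {"lambda1": 2.0, "P": 120.0})

    def test_default_grids_contain_published_fits_inside_bounds(self):
        fits = {"0": {"E_fat": 3.7, "E_glandular": 9.5, "E_skin": 25.0},
                "I": {"lambda1": 2.0, "P": 120.0},
                "II": {"lambda2": 1.2, "alpha0": 0.17},
                "III": {"lambda3": 1.7, "E_scar": 24.0}}
        for phase, truth in fits.items():
            for level in ("reduced", "full"):
                g = default_grids(phase, level)
                for name, val in truth.items():
                    lo, hi = PHASE_BOUNDS[phase][name]
                    assert g[name].min() >= lo and g[name].max() <= hi
                    assert np.min(np.abs(g[name] - val)) < 1e-9


class TestRasterize:
    def test_horizontal_segment_cell_count(self):
        L = 14.0
        seg = np.array([[0.0, 0.0], [L, 0.0]])
        r = rasterize(seg, None, RES)
        assert abs(r.count - np.ceil(L / RES)) <= 1

    def test_empty_contour_raises(self):
        with pytest.raises(ValueError):
            rasterize(np.empty((0, 2)), None, RES)

    def test_doubling_resolution_doubles_cells(self):
        th = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        c = np.column_stack([20 * np.cos(th), 12 * np.sin(th)])
        n1 = rasterize(c, None, RES).count
        n2 = rasterize(c, None, RES / 2).count
        assert 1.8 <= n2 / n1 <= 2.2

    def test_contour_outside_explicit_roi(self):
        seg = np.array([[0.0, 0.0], [5.0, 0.0]])
        with pytest.raises(ValueError):
            rasterize(seg, (10.0, 10.0, 4.0), RES)


class TestObjective:
    def circle(self, r=15.0, n=300):
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return np.column_stack([r * np.cos(th), r * np.sin(th)]) \
            + np.array([30.0, 40.0])

    def test_identical_contours_zero(self):
        c = self.circle()
        assert objective_f(c, c, 1.0, RES) == 0.0

    def test_scale_nuisance_absorbs_prescaling(self):
        c = self.circle()
        assert objective_f(c, c / 2.0, 2.0, RES) == 0.0
        s, f = minimize_s(c, c / 1.3, resolution=RES)
        assert f == 0.0 and abs(s - 1.3) < 0.02

    def test_shifted_copy_matches_brute_force_count(self):
        c = self.circle()
        shifted = c + np.array([RES, 0.0])
        got = objective_f(c, shifted, 1.0, RES)
        # brute force: rasterise by hand on a common grid and count XOR
        allp = np.vstack([c, shifted])
        x0, y0 = allp.min(axis=0) - 0.5 * RES
        size = max(np.ptp(allp[:, 0]), np.ptp(allp[:, 1])) + 2 * RES
        a = rasterize(c, (x0, y0, size), RES).grid
        b = rasterize(shifted, (x0, y0, size), RES).grid
        assert got == np.count_nonzero(a ^ b) > 0

    def test_invariance_to_vertex_order_and_common_translation(self):
        c = self.circle()
        gt = self.circle(r=14.0)
        base = objective_f(c, gt, 1.0, RES)
        rolled = objective_f(np.roll(c, 57, axis=0), gt, 1.0, RES)
        assert rolled == base
        t = np.array([13.37, -4.2])
        # translation applied to both contours moves the auto-ROI with them
        assert objective_f(c + t, gt + t, 1.0, RES) == base


@pytest.fixture(scope="module")
def fixed():
    return FixedParams()


@pytest.fixture(scope="module")
def prior():
    return {"E_fat": 3.7, "E_glandular": 9.5, "E_skin": 25.0}


class TestSimulatePhase:
    def test_missing_prior_rejected(self, label_map, spec, fixed):
        with pytest.raises(ValueError):
            simulate_phase("I", label_map, {"lambda1": 2.0, "P": 120.0},
                           spec=spec, fixed=fixed)

    def test_rigid_limit_approaches_unloaded_shape(self, label_map,
                                                   breast_mesh):
        # stiffness scaled far up: the seated contour converges to the
        # reference outline
        mats = material_table(370.0, 950.0, 2500.0)
        s = solve_equilibrium(breast_mesh, mats, LoadCase())
        dev = np.abs(outer_contour(s) - outer_contour(breast_mesh)).max()
        assert dev < 0.5

    def test_phase1_at_identity_matches_phase0_with_cavity(
            self, label_map, spec, fixed, prior, cavity_spec):
        quiet = FixedParams(delta_inflammation=0.0)
        cI = simulate_phase("I", label_map, {"lambda1": 1.0, "P": 0.0},
                            spec=spec, fixed=quiet, prior=prior)
        mesh = apply_virtual_lumpectomy(build_mesh(label_map,
                                                   quiet.mesh_size),
                                        cavity_spec)
        mats = material_table(prior["E_fat"], prior["E_glandular"],
                              prior["E_skin"])
        ref = outer_contour(solve_equilibrium(mesh, mats, LoadCase()))
        assert objective_f(cI, ref, 1.0, RES) == 0.0


class TestFitPhase:
    def test_noiseless_grid_aligned_truth_recovered_exactly(
            self, label_map, spec, fixed, prior):
        truth = {"lambda1": 2.0, "P": 120.0}
        obs = generate_observation(label_map, "I", truth, seed=3, spec=spec,
                                   fixed=fixed, prior=prior)
        fit = fit_phase("I", obs, {"lambda1": np.array([1.5, 2.0, 2.5]),
                                   "P": np.array([40.0, 120.0, 200.0])},
                        label_map=label_map, spec=spec, fixed=fixed,
                        prior=prior)
        assert fit.argmin == truth
        assert fit.f_min == 0.0

    def test_off_grid_truth_recovered_within_one_cell(
            self, label_map, spec, fixed, prior):
        truth = {"lambda1": 2.1, "P": 120.0}
        obs = generate_observation(label_map, "I", truth, seed=3, spec=spec,
                                   fixed=fixed, prior=prior)
        grid = {"lambda1": np.array([1.5, 2.0, 2.5]),
                "P": np.array([40.0, 120.0, 200.0])}
        fit = fit_phase("I", obs, grid, label_map=label_map, spec=spec,
                        fixed=fixed, prior=prior)
        assert abs(fit.argmin["lambda1"] - 2.1) <= 0.5 + 1e-9
        assert abs(fit.argmin["P"] - 120.0) <= 80.0 + 1e-9

    def test_grid_outside_bounds_rejected(self, label_map, spec, fixed,
                                          prior):
        with pytest.raises(ValueError):
            fit_phase("I", np.zeros((4, 2)),
                      {"lambda1": np.array([0.5, 1.0]),
                       "P": np.array([0.0])},
                      label_map=label_map, spec=spec, fixed=fixed,
                      prior=prior)


def test_run_full_study_rejects_out_of_order_phases():
    with pytest.raises(ValueError):
        run_full_study({"phases": ["0", "II"]})
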