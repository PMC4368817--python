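"""Unit-cell geometry, wall ramp, and the finite-volume ADI solver."""

import numpy as np
import pytest

from epperm.pk import PKParams, civ_profile
from epperm.transport import (
    TransportParams,
    UnitCellGeometry,
    WallPermeabilityFunction,
    build_box_grid,
    build_grid,
    dwall_at,
    evolve,
    signal_model,
    solve_forward,
)

WALL = WallPermeabilityFunction(t_ep=1030.0, t_del=1090.0, t_sat=1390.0, d_sat=0.008)


class TestWallRamp:
    def test_zero_before_delay(self):
        assert dwall_at(WALL.t_ep, WALL) == 0.0
        assert dwall_at(WALL.t_del, WALL) == 0.0

    def test_linear_midpoint(self):
        assert dwall_at((WALL.t_del + WALL.t_sat) / 2, WALL) == pytest.approx(WALL.d_sat / 2)

    def test_saturates(self):
        assert dwall_at(WALL.t_sat, WALL) == WALL.d_sat
        assert dwall_at(WALL.t_sat + 1e6, WALL) == WALL.d_sat

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            WallPermeabilityFunction(t_ep=100.0, t_del=50.0, t_sat=200.0, d_sat=0.01)
        with pytest.raises(ValueError):
            WallPermeabilityFunction(t_ep=0.0, t_del=100.0, t_sat=100.0, d_sat=0.01)


class TestGeometry:
    def test_default_layer_depths(self):
        g = UnitCellGeometry()
        # four layers from depth h downward, spaced a*sqrt(3)/2; last one at H - h
        np.testing.assert_allclose(g.layer_depths, [72.0, 123.96, 175.92, 227.88], atol=0.01)
        assert g.layer_depths[-1] == pytest.approx(g.H - g.h, abs=0.15)

    def test_overlapping_capillaries_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            UnitCellGeometry(r=20.0, w=15.0)

    def test_unresolved_wall_rejected(self):
        with pytest.raises(ValueError, match="resolve"):
            build_grid(UnitCellGeometry(), resolution=2.0)

    def test_lumen_area_per_capillary(self):
        g = build_grid(UnitCellGeometry(), resolution=0.5)
        assert g.lumen_area_per_capillary == pytest.approx(np.pi * 3.5**2, rel=0.05)

    def test_unit_cell_dimensions(self):
        g = build_grid(UnitCellGeometry(), resolution=1.0)
        assert g.width == pytest.approx(30.0)
        assert g.height == pytest.approx(300.0)
        assert g.n_capillary_sections == 4


@pytest.fixture(scope="module")
def small_grid():
    return build_box_grid(20.0, 20.0, [(10.0, 10.0)], 3.5, 1.0, 1.0)


def const_one(t):
    return np.ones_like(np.asarray(t, dtype=float))


class TestForwardSolver:
    def test_impermeable_wall_gives_zero_extravasation(self, small_grid):
        wall = WallPermeabilityFunction(t_ep=0.0, t_del=0.0, t_sat=100.0, d_sat=0.0)
        sol = solve_forward(small_grid, TransportParams(30.0, wall), const_one, np.linspace(0, 1000, 11))
        assert np.all(sol.m_ev == 0.0)
        np.testing.assert_array_equal(sol.m_total, sol.m_iv)

    def test_equilibration_to_boundary_concentration(self, small_grid):
        wall = WallPermeabilityFunction(t_ep=0.0, t_del=0.0, t_sat=100.0, d_sat=1.0)
        sol = solve_forward(small_grid, TransportParams(30.0, wall), const_one, np.array([0.0, 5e4]), dt=50.0)
        assert sol.m_ev[-1] / small_grid.tissue_area == pytest.approx(1.0, rel=1e-3)

    def test_monotone_influx_while_boundary_exceeds_tissue(self, small_grid):
        # c_iv = 1 throughout: tissue concentration can never exceed it
        wall = WallPermeabilityFunction(t_ep=0.0, t_del=0.0, t_sat=300.0, d_sat=0.02)
        sol = solve_forward(small_grid, TransportParams(5.0, wall), const_one, np.linspace(0, 2000, 81))
        assert np.all(np.diff(sol.m_ev) >= -1e-12)

    def test_mass_conserved_with_sealed_lumen(self, small_grid):
        sealed = small_grid.sealed()
        rng = np.random.default_rng(7)
        c0 = rng.random(sealed.shape)
        zero = lambda t: np.zeros_like(np.asarray(t, dtype=float))
        _, mass, _ = evolve(
            sealed, 30.0, lambda t: np.full_like(np.asarray(t, float), 0.05), zero,
            0.0, 500.0, 10.0, c0=c0, dirichlet_lumen=False, mass_over="wall+tissue",
        )
        m0 = float((c0 * (sealed.cell_type != 2)).sum()) * sealed.cell_area
        drift = np.abs(np.diff(np.concatenate([[m0], mass]))) / m0
        assert drift.max() < 1e-10

    def test_wall_limited_flux_scales_linearly_with_dsat(self):
        # wall-limited regime (d_sat three orders below d_tiss): once the thin
        # wall has charged (t >> w^2/d_sat), the extravasation rate divided by
        # the driving difference (1 - mean tissue concentration) is
        # proportional to d_sat
        grid = build_box_grid(60.0, 60.0, [(30.0, 30.0)], 3.5, 1.0, 1.0)
        rates = []
        for d_sat in (0.002, 0.004, 0.008):
            wall = WallPermeabilityFunction(t_ep=0.0, t_del=0.0, t_sat=1.0, d_sat=d_sat)
            sol = solve_forward(
                grid, TransportParams(30.0, wall), const_one, np.array([1500.0, 2000.0, 2500.0]), dt=5.0
            )
            slope = (sol.m_ev[2] - sol.m_ev[0]) / 1000.0
            backpressure = sol.m_ev[1] / grid.tissue_area
            rates.append(slope / (1.0 - backpressure))
        ratios = np.array(rates[1:]) / np.array(rates[:-1])
        np.testing.assert_allclose(ratios, 2.0, rtol=0.02)


class TestSignalModel:
    def test_control_signal_is_normalized_miv(self, schedule):
        grid = build_grid(UnitCellGeometry(), 1.0)
        civ = civ_profile(PKParams(), schedule.t_fd)
        t = schedule.frame_times()
        wall = WallPermeabilityFunction(t_ep=schedule.t_ep, t_del=schedule.t_ep, t_sat=schedule.t_ep + 1, d_sat=0.0)
        sol = solve_forward(grid, TransportParams(30.0, wall), civ, t)
        sig = signal_model(sol, schedule.t_ep)
        np.testing.assert_allclose(sig, sol.m_iv / sol.m_iv[t < schedule.t_ep].max())
        assert sig[t < schedule.t_ep].max() == pytest.approx(1.0)

    def test_ep_signal_matches_control_before_delay(self, schedule, noiseless_ds):
        grid = build_grid(UnitCellGeometry(), 1.0)
        civ = civ_profile(PKParams(), schedule.t_fd)
        t = schedule.frame_times()
        ep = solve_forward(grid, TransportParams(30.0, noiseless_ds.truth.wall), civ, t)
        control = solve_forward(
            grid,
            TransportParams(30.0, WallPermeabilityFunction(schedule.t_ep, schedule.t_ep, schedule.t_ep + 1, 0.0)),
            civ,
            t,
        )
        pre_delay = t < noiseless_ds.truth.wall.t_del
        np.testing.assert_allclose(
            signal_model(ep, schedule.t_ep)[pre_delay],
            signal_model(control, schedule.t_ep)[pre_delay],
            atol=1e-12,
        )

    def test_missing_normalization_window_rejected(self, small_grid):
        wall = WallPermeabilityFunction(t_ep=0.0, t_del=0.0, t_sat=100.0, d_sat=0.01)
        sol = solve_forward(small_grid, TransportParams(30.0, wall), const_one, np.array([500.0, 600.0]))
        with pytest.raises(ValueError, match="pre-pulse"):
            signal_model(sol, t_ep=100.0)
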