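"""Monodomain solver: stencils, stability, phase field, propagation."""

import numpy as np
import pytest

from cardioviz.tissue_solver import (
    DiffusionParams, PhaseField, StimulusEvent, StimulusProtocol, TissueGrid,
    divergence_phi_flux, double_well, double_well_deriv, laplacian_3d,
    relax_phase_field, run_tissue_simulation, stability_max_dt, step_tissue,
)


class TestStabilityBound:
    def test_reference_3d_bound(self):
        # 0.33 mm, 0.154 mm^2/ms, d = 3 -> 0.118 ms (3 significant figures)
        assert stability_max_dt(0.33, 0.154, 3) == pytest.approx(0.118, abs=5e-4)

    def test_direct_arithmetic_1d(self):
        assert stability_max_dt(0.33, 0.154, 1) == pytest.approx(
            0.33 ** 2 / (2 * 0.154), rel=1e-12)

    def test_halving_spacing_quarters_bound(self):
        assert stability_max_dt(0.165, 0.1, 3) == pytest.approx(
            stability_max_dt(0.33, 0.1, 3) / 4, rel=1e-12)

    @pytest.mark.parametrize("args", [(0, 0.1, 3), (0.33, -1, 3), (0.33, 0.1, 4)])
    def test_rejects_bad_arguments(self, args):
        with pytest.raises(ValueError):
            stability_max_dt(*args)


class TestLaplacian:
    def test_constant_field_is_zero(self):
        assert np.allclose(laplacian_3d(np.full((5, 5, 5), 7.3), 0.33), 0.0)

    def test_exact_for_quadratic(self):
        # f = (i*dx)^2 has second difference exactly 2 on interior voxels
        nx = 7
        dx = 0.5
        x = np.arange(nx) * dx
        f = np.broadcast_to((x ** 2)[:, None, None], (nx, 5, 5)).copy()
        lap = laplacian_3d(f, dx)
        assert np.allclose(lap[1:-1, 1:-1, 1:-1], 2.0, atol=1e-12)

    def test_matches_brute_force_stencil(self, rng):
        f = rng.normal(size=(5, 6, 7))
        sp = (0.3, 0.4, 0.5)
        lap = laplacian_3d(f, sp)
        for i in range(1, 4):
            for j in range(1, 5):
                for k in range(1, 6):
                    expect = ((f[i - 1, j, k] - 2 * f[i, j, k] + f[i + 1, j, k]) / sp[0] ** 2
                              + (f[i, j - 1, k] - 2 * f[i, j, k] + f[i, j + 1, k]) / sp[1] ** 2
                              + (f[i, j, k - 1] - 2 * f[i, j, k] + f[i, j, k + 1]) / sp[2] ** 2)
                    assert lap[i, j, k] == pytest.approx(expect, rel=1e-12)

    def test_rejects_small_dims(self):
        with pytest.raises(ValueError, match="dims"):
            laplacian_3d(np.zeros((2, 5, 5)), 0.33)


class TestDivergenceOperator:
    def test_matches_triple_loop_oracle_bit_exact(self, rng):
        """Vectorized divergence-form operator == naive flux loop, bitwise."""
        V = rng.normal(size=(6, 7, 8)) * 50
        phi = rng.random((6, 7, 8))
        phi[phi < 0.3] = 0.0  # some inactive voxels
        D = 0.154
        sp = (0.33, 0.4, 0.25)
        got = divergence_phi_flux(V, phi, D, sp)

        expect = np.zeros_like(V)
        c = [D / s ** 2 for s in sp]
        # mirror the axis-by-axis accumulation: all right-face additions of
        # one axis, then all left-face subtractions, as the vectorized
        # operator applies them
        for axis in range(3):
            fluxes = {}
            for idx in np.ndindex(*V.shape):
                nxt = list(idx); nxt[axis] += 1
                if nxt[axis] < V.shape[axis]:
                    nxt = tuple(nxt)
                    pa, pb = phi[idx], phi[nxt]
                    pf = 0.0 if (pa == 0.0 or pb == 0.0) else 0.5 * (pa + pb)
                    fluxes[idx] = pf * (V[nxt] - V[idx]) * c[axis]
            for idx, flux in fluxes.items():
                expect[idx] += flux
            for idx, flux in fluxes.items():
                nxt = list(idx); nxt[axis] += 1
                expect[tuple(nxt)] -= flux
        assert np.array_equal(got, expect)

    def test_uniform_field_no_change(self):
        mask = np.ones((6, 6, 6), bool)
        grid = TissueGrid(mask, spacing=0.33)
        phase = PhaseField(phi=mask.astype(float))
        grid.vm_field[:] = -40.0
        grid.S[0] = -40.0
        before = grid.vm_field.copy()
        step_tissue(grid, phase, DiffusionParams(), None, 0.0, 0.02,
                    reaction=False)
        assert np.array_equal(grid.vm_field, before)

    def test_heterogeneous_D_reduces_to_scalar_when_uniform(self, rng):
        V = rng.normal(size=(6, 6, 6)) * 30
        phi = rng.random((6, 6, 6))
        phi[phi < 0.2] = 0.0
        ref = divergence_phi_flux(V, phi, 0.154, 0.33)
        het = divergence_phi_flux(V, phi, 0.154, 0.33,
                                  D_field=np.full(V.shape, 0.154))
        np.testing.assert_allclose(het, ref, rtol=1e-12, atol=1e-12)

    def test_heterogeneous_D_conserves(self, rng):
        mask = np.ones((10, 10, 10), bool)
        phase = relax_phase_field(mask)
        grid = TissueGrid(mask, spacing=0.33)
        grid.vm_field[:] = rng.normal(size=mask.shape) * 40
        grid.S[0] = grid.vm_field.ravel()[grid.tissue_idx]
        D_field = np.full(mask.shape, 0.154)
        D_field[:5] = 0.02  # slow-conduction half
        phi_eff = phase.phi_eff
        total0 = float((phi_eff * grid.vm_field).sum())
        cache = {}
        for k in range(100):
            step_tissue(grid, phase, DiffusionParams(), None, k * 0.02, 0.02,
                        reaction=False, D_field=D_field, _cache=cache)
        total1 = float((phi_eff * grid.vm_field).sum())
        assert abs(total1 - total0) <= 1e-10 * max(abs(total0), 1.0)

    def test_no_flux_conservation(self, rng):
        """sum(phi_eff * Vm) is invariant under reaction-free stepping."""
        mask = rng.random((16, 16, 16)) > 0.5
        phase = relax_phase_field(mask)
        grid = TissueGrid(mask, spacing=0.33)
        grid.vm_field[:] = rng.normal(size=mask.shape) * 40
        grid.S[0] = grid.vm_field.ravel()[grid.tissue_idx]
        phi_eff = phase.phi_eff
        total0 = float((phi_eff * grid.vm_field).sum())
        cache = {}
        for k in range(200):
            step_tissue(grid, phase, DiffusionParams(), None, k * 0.02, 0.02,
                        reaction=False, _cache=cache)
            total = float((phi_eff * grid.vm_field).sum())
            assert abs(total - total0) <= 1e-10 * max(abs(total0), 1.0)


class TestPhaseField:
    def test_double_well_minima(self):
        assert double_well(0.0) == pytest.approx(-0.25)
        assert double_well(1.0) == pytest.approx(-0.25)
        assert double_well(0.5) == pytest.approx(0.0)
        assert double_well_deriv(0.0) == 0.0
        assert double_well_deriv(1.0) == 0.0

    def test_all_true_mask_is_fixed_point(self):
        pf = relax_phase_field(np.ones((5, 5, 5), bool), n_iter=50)
        assert np.allclose(pf.phi, 1.0, atol=1e-12)

    def test_bounded_and_plateaued(self):
        mask = np.zeros((24, 24, 24), bool)
        mask[6:18, 6:18, 6:18] = True
        pf = relax_phase_field(mask)
        assert pf.phi.min() >= 0.0 and pf.phi.max() <= 1.0
        assert pf.phi[12, 12, 12] > 1 - 1e-3   # deep inside
        assert pf.phi[0, 0, 0] < 1e-3          # deep outside

    def test_ball_profile_monotone_across_interface(self):
        mask = np.zeros((30, 30, 30), bool)
        x = np.arange(30) - 14.5
        r = np.sqrt(x[:, None, None] ** 2 + x[None, :, None] ** 2
                    + x[None, None, :] ** 2)
        mask[r < 9] = True
        pf = relax_phase_field(mask)
        shells = [pf.phi[(r >= a) & (r < a + 1)].mean() for a in range(1, 14)]
        assert all(b <= a + 1e-12 for a, b in zip(shells, shells[1:]))

    def test_divergence_raises_with_advice(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True  # interface present, so large dt oscillates
        with pytest.raises(FloatingPointError, match="relax_dt"):
            relax_phase_field(mask, relax_dt=5.0, n_iter=50)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            relax_phase_field(np.zeros((4, 4, 4), bool))


class TestStepping:
    def test_cfl_violation_refused_with_bound(self):
        mask = np.ones((6, 6, 6), bool)
        grid = TissueGrid(mask)
        phase = PhaseField(phi=mask.astype(float))
        with pytest.raises(ValueError, match="stability bound"):
            run_tissue_simulation(grid, phase, DiffusionParams(), None,
                                  duration=1.0, dt=0.2)

    def test_unordered_protocol_rejected(self):
        r = np.ones((4, 4, 4), bool)
        with pytest.raises(ValueError, match="time-ordered"):
            StimulusProtocol((StimulusEvent(10, 2, -52, r),
                              StimulusEvent(0, 2, -52, r)))

    def test_protocol_region_must_touch_tissue(self):
        mask = np.ones((6, 6, 6), bool)
        grid = TissueGrid(mask)
        phase = relax_phase_field(mask)
        region = np.zeros((6, 6, 6), bool)  # empty region
        with pytest.raises(ValueError, match="intersect"):
            run_tissue_simulation(grid, phase, DiffusionParams(),
                                  StimulusProtocol.single(region),
                                  duration=1.0)

    def test_no_stimulus_stays_at_rest(self):
        mask = np.ones((8, 8, 8), bool)
        grid = TissueGrid(mask)
        phase = relax_phase_field(mask)
        run = run_tissue_simulation(grid, phase, DiffusionParams(), None,
                                    duration=20.0, snapshot_interval=5.0)
        rest = grid.S[0, 0]
        for snap in run.snapshots:
            assert np.all(np.abs(snap[mask] - rest) < 0.5)
        assert np.all(np.isnan(run.activation_map))


@pytest.fixture(scope="module")
def cable_run():
    mask = np.pad(np.ones((60, 3, 3), bool), 2)
    phase = relax_phase_field(mask)
    grid = TissueGrid(mask, spacing=0.33)
    s1 = np.zeros_like(mask)
    s1[2:7] = True
    return run_tissue_simulation(
        grid, phase, DiffusionParams(), StimulusProtocol.single(s1),
        duration=45.0, snapshot_interval=15.0)


class TestCablePropagation:
    def test_activation_monotone_with_distance(self, cable_run):
        line = cable_run.activation_map[:, 3, 3]
        interior = line[8:-8]
        assert np.all(np.isfinite(interior))
        assert np.all(np.diff(interior) > 0)

    def test_conduction_velocity_physiological(self, cable_run):
        line = cable_run.activation_map[:, 3, 3]
        cv = 0.33 * (50 - 15) / (line[52] - line[17])
        # human ventricular CV ~ 0.5-0.9 mm/ms at D = 0.154 mm^2/ms
        assert 0.4 < cv < 0.9

    def test_mesh_refinement_cv_stable(self):
        """CV changes < 10% when dx halves (dt fixed, still below both bounds)."""
        cvs = []
        for n, dx in ((60, 0.33), (120, 0.165)):
            mask = np.pad(np.ones((n, 3, 3), bool), 2)
            phase = relax_phase_field(mask, xi=dx, spacing=dx)
            grid = TissueGrid(mask, spacing=dx)
            s1 = np.zeros_like(mask)
            s1[2:7] = True
            run = run_tissue_simulation(
                grid, phase, DiffusionParams(), StimulusProtocol.single(s1),
                duration=45.0, snapshot_interval=45.0)
            line = run.activation_map[:, 3, 3]
            lo, hi = int(0.3 * n), int(0.8 * n)
            cvs.append(dx * (hi - lo) / (line[hi + 2] - line[lo + 2]))
        assert abs(cvs[1] - cvs[0]) / cvs[0] < 0.10


class TestDiffusionParams:
    def test_factor_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            DiffusionParams(D_global=0.2, K=0.154, R_m=1.0, Cm=1.0)
        dp = DiffusionParams.from_factors(K=0.154, R_m=1.0, Cm=1.0)
        assert dp.D_global == pytest.approx(0.154)

    def test_rejects_nonpositive_D(self):
        with pytest.raises(ValueError):
            DiffusionParams(D_global=0.0)
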