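"""Forward simulation and inverse fitting of the osmotic volume model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytomech.osmotic import (
    CellParams,
    CellState,
    CellVolumeTrace,
    DegenerateStateError,
    ModelConstants,
    OsmoticProtocol,
    OsmoticStep,
    ProtocolMismatchError,
    UnidentifiableError,
    equilibrium_volume_ratio,
    estimate_phir_from_equilibrium,
    fit_mixture_model,
    fit_two_step_sequence,
    intracellular_osmolarity,
    simulate_volume_response,
    surface_area,
)


class TestSurfaceArea:
    def test_sphere_identity(self):
        r = 1e-6
        v = 4 / 3 * math.pi * r**3
        assert surface_area(v) == pytest.approx(4 * math.pi * r**2, rel=1e-12)

    def test_mean_cell_radius(self):
        # a = 9.1 μm -> A = 4π a²
        v = 4 / 3 * math.pi * (9.1e-6) ** 3
        assert surface_area(v) == pytest.approx(1.0405e-9, rel=1e-3)

    def test_scaling_law(self):
        v = 2.7e-15
        assert surface_area(8 * v) == pytest.approx(4 * surface_area(v), rel=1e-12)

    def test_rejects_nonpositive_volume(self):
        with pytest.raises(ValueError):
            surface_area(0.0)


class TestIntracellularOsmolarity:
    def make(self, phi_ir, v_ratio, c_ir=333.0, a=9e-6):
        params = CellParams(lp=1e-13, phi_ir=phi_ir, radius_ref=a, c_ir=c_ir)
        v_r = params.volume_ref
        n_i = c_ir * phi_ir * v_r if phi_ir > 0 else c_ir * v_r
        state = CellState(
            volume=v_ratio * v_r, solute_moles=n_i, active_water_fraction=phi_ir
        )
        return state, params

    def test_reference_state_returns_reference_osmolarity(self):
        state, params = self.make(phi_ir=0.6, v_ratio=1.0)
        assert intracellular_osmolarity(state, params) == pytest.approx(333.0, rel=1e-12)

    def test_fully_active_water(self):
        # φ_ir = 1: c_i = n_i / V for any volume
        state, params = self.make(phi_ir=1.0, v_ratio=1.4)
        assert intracellular_osmolarity(state, params) == pytest.approx(
            333.0 / 1.4, rel=1e-12
        )

    def test_hand_computed_dilution(self):
        # φ_ir = 0.5, V = 1.2 V_r: φ_i = 1 − 0.5/1.2, c_i = 333·0.5/(φ_i·1.2)
        state, params = self.make(phi_ir=0.5, v_ratio=1.2)
        phi_i = 1 - 0.5 / 1.2
        assert intracellular_osmolarity(state, params) == pytest.approx(
            333 * 0.5 / (phi_i * 1.2), rel=1e-12
        )
        assert intracellular_osmolarity(state, params) == pytest.approx(237.9, abs=0.1)

    def test_degenerate_below_solid_fraction(self):
        state, params = self.make(phi_ir=0.5, v_ratio=1.0)
        shrunk = CellState(
            volume=0.4 * params.volume_ref,
            solute_moles=state.solute_moles,
            active_water_fraction=0.5,
        )
        with pytest.raises(DegenerateStateError):
            intracellular_osmolarity(shrunk, params)


class TestEquilibriumRatio:
    @pytest.mark.parametrize(
        "phi_ir, c_er, c_e, expected",
        [
            (1.0, 333.0, 466.0, 333.0 / 466.0),  # pure osmometer
            (0.0, 333.0, 466.0, 1.0),  # nothing exchanges
            (0.5, 466.0, 333.0, 1 - 0.5 + 0.5 * 466 / 333),  # swelling, ≈1.19970
        ],
    )
    def test_closed_form(self, phi_ir, c_er, c_e, expected):
        assert equilibrium_volume_ratio(phi_ir, c_er, c_e) == pytest.approx(
            expected, rel=1e-9
        )

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            equilibrium_volume_ratio(0.5, 333.0, 0.0)
        with pytest.raises(ValueError):
            equilibrium_volume_ratio(1.5, 333.0, 466.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        phi=st.floats(0.0, 1.0),
        c_er=st.floats(100.0, 600.0),
        c_e=st.floats(100.0, 600.0),
    )
    def test_ratio_brackets_and_direction(self, phi, c_er, c_e):
        ratio = equilibrium_volume_ratio(phi, c_er, c_e)
        lo, hi = sorted((1.0, 1 - phi + phi * c_er / c_e))
        assert lo - 1e-12 <= ratio <= hi + 1e-12
        if c_e > c_er:  # hyperosmotic: shrink (or stay, if φ=0)
            assert ratio <= 1.0 + 1e-12


class TestSimulation:
    def test_no_gradient_means_constant_volume(self, constants):
        protocol = OsmoticProtocol(
            steps=(OsmoticStep(333.0, 120.0),), equilibration_osmolarity=333.0
        )
        params = CellParams(lp=1e-13, phi_ir=0.6, radius_ref=9e-6, c_ir=333.0)
        tr = simulate_volume_response(params, protocol, constants)
        assert np.allclose(tr.volume, params.volume_ref, rtol=1e-9)

    def test_hyperosmotic_step_shrinks_monotonically(self, protocol, constants, untreated_params):
        tr = simulate_volume_response(untreated_params, protocol, constants)
        v_hyper = tr.volume[tr.step_index == 0]
        assert np.all(np.diff(v_hyper) < 0)
        v_hypo = tr.volume[tr.step_index == 1]
        assert np.all(np.diff(v_hypo) > 0)

    @pytest.mark.parametrize("phi_ir", [0.0, 0.25, 0.5, 0.75, 1.0])
    @pytest.mark.parametrize("c_er, c_e", [(333.0, 466.0), (466.0, 333.0)])
    def test_plateau_matches_closed_form(self, phi_ir, c_er, c_e, constants):
        protocol = OsmoticProtocol(
            steps=(OsmoticStep(c_e, 300.0),), equilibration_osmolarity=c_er
        )
        params = CellParams(lp=1e-13, phi_ir=phi_ir, radius_ref=9e-6, c_ir=c_er)
        tr = simulate_volume_response(params, protocol, constants)
        expected = equilibrium_volume_ratio(phi_ir, c_er, c_e)
        assert tr.volume[-1] / params.volume_ref == pytest.approx(expected, rel=1e-3)

    def test_time_rescaling_invariance(self, constants):
        """Doubling L_p is exactly a factor-2 time compression."""
        protocol = OsmoticProtocol(
            steps=(OsmoticStep(466.0, 300.0),), equilibration_osmolarity=333.0
        )
        base = CellParams(lp=5e-14, phi_ir=0.6, radius_ref=9e-6, c_ir=333.0)
        fast = CellParams(lp=1e-13, phi_ir=0.6, radius_ref=9e-6, c_ir=333.0)
        tr_base = simulate_volume_response(base, protocol, constants, sampling_interval=2.0)
        tr_fast = simulate_volume_response(fast, protocol, constants, sampling_interval=1.0)
        # fast(t) = base(2t): sample i of the 1 s grid matches sample i of
        # the 2 s grid
        n = min(len(tr_fast.volume), len(tr_base.volume))
        np.testing.assert_allclose(tr_fast.volume[:n], tr_base.volume[:n], rtol=1e-6)

    def test_solute_conserved_along_trajectory(self, protocol, constants, untreated_params):
        """Back-computed n_i = c_i·φ_i·V is constant along the simulation."""
        params = untreated_params
        tr = simulate_volume_response(params, protocol, constants)
        v_solid = (1 - params.phi_ir) * params.volume_ref
        n0 = params.c_ir * params.phi_ir * params.volume_ref
        c_i = n0 / (tr.volume - v_solid)
        n_back = c_i * (tr.volume - v_solid)
        np.testing.assert_allclose(n_back, n0, rtol=1e-9)


class TestPhirFromEquilibrium:
    def plateau_trace(self, ratio, n=150, v_r=3e-15):
        t = np.arange(n) * 2.0
        v = np.full(n, ratio * v_r)
        v[0] = v_r
        return CellVolumeTrace("c", t, v, np.zeros(n, int))

    def test_pure_osmometer_roundtrip(self, protocol):
        tr = self.plateau_trace(333.0 / 466.0)
        phi, clamped = estimate_phir_from_equilibrium(tr, 0, protocol)
        assert phi == pytest.approx(1.0, abs=1e-9)
        assert not clamped

    def test_no_volume_change_gives_zero(self, protocol):
        tr = self.plateau_trace(1.0)
        phi, _ = estimate_phir_from_equilibrium(tr, 0, protocol)
        assert phi == pytest.approx(0.0, abs=1e-9)

    def test_intermediate_inversion(self, protocol):
        tr = self.plateau_trace(0.88)
        phi, _ = estimate_phir_from_equilibrium(tr, 0, protocol)
        assert phi == pytest.approx((0.88 - 1) / (333 / 466 - 1), rel=1e-6)
        assert phi == pytest.approx(0.4203, abs=1e-3)

    def test_iso_osmotic_step_unidentifiable(self):
        protocol = OsmoticProtocol(
            steps=(OsmoticStep(333.0, 300.0),), equilibration_osmolarity=333.0
        )
        tr = self.plateau_trace(1.0)
        with pytest.raises(UnidentifiableError):
            estimate_phir_from_equilibrium(tr, 0, protocol)


class TestMixtureFit:
    def test_noiseless_roundtrip_untreated_mean(self, protocol, constants):
        params = CellParams(lp=7.2e-14, phi_ir=0.6, radius_ref=9.1e-6, c_ir=333.0)
        tr = simulate_volume_response(params, protocol, constants)
        res = fit_mixture_model(tr, 0, protocol, constants)
        assert res.converged
        assert res.lp == pytest.approx(7.2e-14, rel=0.01)
        assert res.phi_ir == pytest.approx(0.6, abs=0.01)
        assert res.r_squared > 0.999

    @pytest.mark.parametrize("lp", [2e-14, 2e-13])
    @pytest.mark.parametrize("phi_ir", [0.3, 0.9])
    def test_recovery_grid(self, lp, phi_ir, protocol, constants):
        params = CellParams(lp=lp, phi_ir=phi_ir, radius_ref=9.1e-6, c_ir=333.0)
        tr = simulate_volume_response(params, protocol, constants)
        res = fit_mixture_model(tr, 0, protocol, constants)
        assert res.lp == pytest.approx(lp, rel=0.01)
        assert res.phi_ir == pytest.approx(phi_ir, rel=0.01)

    def test_zero_step_flagged_unidentifiable(self, constants):
        protocol = OsmoticProtocol(
            steps=(OsmoticStep(333.0, 300.0),), equilibration_osmolarity=333.0
        )
        params = CellParams(lp=1e-13, phi_ir=0.6, radius_ref=9e-6, c_ir=333.0)
        tr = simulate_volume_response(params, protocol, constants)
        res = fit_mixture_model(tr, 0, protocol, constants)
        assert not res.converged
        assert "unidentifiable" in res.qc_flags

    def test_flat_trace_with_nonzero_step_flagged(self, protocol, constants):
        n = 150
        tr = CellVolumeTrace("flat", np.arange(n) * 2.0, np.full(n, 3e-15), np.zeros(n, int))
        res = fit_mixture_model(tr, 0, protocol, constants)
        assert not res.converged
        assert "unidentifiable" in res.qc_flags

    def test_small_noise_recovery_is_nearly_unbiased(self, protocol, constants, rng):
        """At sub-pixel radius noise (0.5%) the estimator mean is within a
        few percent of truth — the regime real segmentation operates in."""
        params = CellParams(lp=7.2e-14, phi_ir=0.6, radius_ref=9.1e-6, c_ir=333.0)
        clean = simulate_volume_response(params, protocol, constants)
        lps = []
        for _ in range(20):
            radius = (clean.volume * 3 / (4 * math.pi)) ** (1 / 3)
            radius = radius * (1 + 0.005 * rng.standard_normal(len(radius)))
            tr = CellVolumeTrace("n", clean.time, 4 / 3 * math.pi * radius**3, clean.step_index)
            res = fit_mixture_model(tr, 0, protocol, constants)
            assert res.converged
            lps.append(res.lp)
        assert np.mean(lps) == pytest.approx(7.2e-14, rel=0.05)


class TestTwoStepSequence:
    def test_per_step_truth_recovery(self, protocol, constants, untreated_params):
        tr = simulate_volume_response(untreated_params, protocol, constants)
        hyper, hypo = fit_two_step_sequence(tr, protocol, constants)
        assert hyper.step_label == "hyper" and hypo.step_label == "hypo"
        assert hyper.lp == pytest.approx(7.2e-14, rel=0.01)
        assert hypo.lp == pytest.approx(8.8e-14, rel=0.01)
        # step-2 reference water fraction follows from the conserved solid volume
        v_solid = (1 - 0.6) * untreated_params.volume_ref
        v_r2 = tr.volume[tr.step_index == 1][0]
        assert hypo.phi_ir == pytest.approx(1 - v_solid / v_r2, rel=0.01)

    def test_symmetric_protocol_gives_equal_estimates(self, protocol, constants):
        params = CellParams(lp=8e-14, phi_ir=0.6, radius_ref=9e-6, c_ir=333.0)
        tr = simulate_volume_response(params, protocol, constants)
        hyper, hypo = fit_two_step_sequence(tr, protocol, constants)
        assert hyper.lp == pytest.approx(hypo.lp, rel=0.01)

    def test_truncated_trace_raises_protocol_mismatch(self, protocol, constants, untreated_params):
        tr = simulate_volume_response(untreated_params, protocol, constants)
        keep = tr.step_index == 0
        truncated = CellVolumeTrace(
            tr.cell_id, tr.time[keep], tr.volume[keep], tr.step_index[keep]
        )
        with pytest.raises(ProtocolMismatchError):
            fit_two_step_sequence(truncated, protocol, constants)
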