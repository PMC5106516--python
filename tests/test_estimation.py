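"""Calibration pipeline: extraction, force differences, pathway estimator,
stiffness fitting, sensitivity and ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epimuscular import (
    ForceWaveform,
    SyntheticSpec,
    c_sensitivity,
    calibrate_group,
    delta_F_LGPL,
    delta_F_SO,
    estimate_pathway_forces,
    estimate_r,
    extract_isometric,
    fit_piecewise_stiffness,
    generate_calibration_dataset,
    generate_waveform,
    pathway_ratios,
)
from epimuscular.core import PiecewiseStiffness
from epimuscular.estimation import CHANNELS, PathwayForceEstimates
from epimuscular.exceptions import (
    ExtractionError,
    ParameterError,
    StructuralError,
)

POSITIONS = np.array([-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0])

series3 = st.lists(
    st.floats(min_value=-5.0, max_value=5.0, allow_nan=False),
    min_size=7,
    max_size=7,
)


def _waveform(profile, stim_onset=2.0, stim_offset=2.5, fs=1000.0, twitches=()):
    """Build a waveform with the same profile on all channels."""
    n = int(3.0 * fs) + 1
    t = np.arange(n) / fs
    f = profile(t)
    return ForceWaveform(
        time_s=t,
        forces_N={ch: f.copy() for ch in CHANNELS},
        stim_onset_s=stim_onset,
        stim_offset_s=stim_offset,
        twitch_times_s=twitches,
    )


class TestExtractIsometric:
    def test_constant_levels(self):
        wf = _waveform(lambda t: np.where(t >= 2.0, 5.0, 1.0))
        out = extract_isometric(wf)
        for ch in CHANNELS:
            assert out[ch].passive_N == pytest.approx(1.0, abs=1e-12)
            assert out[ch].total_N == pytest.approx(5.0, abs=1e-12)

    def test_mean_of_linear_ramp(self):
        # Plateau ramps 4.9 -> 5.1 N over the last 50 ms; the mean is 5.0.
        def profile(t):
            f = np.full_like(t, 1.0)
            f[t >= 2.0] = 4.9
            m = t >= 2.45
            f[m] = 4.9 + 0.2 * (t[m] - 2.45) / 0.05
            return f

        out = extract_isometric(_waveform(profile))
        assert out["f_lgpl_prox"].total_N == pytest.approx(5.0, abs=2e-3)

    def test_synthetic_plateau_matches_configuration(self, noiseless_spec):
        wf = generate_waveform(noiseless_spec, position_mm=0.0)
        out = extract_isometric(wf)
        assert out["f_lgpl_prox"].total_N == pytest.approx(11.5, abs=1e-12)
        assert out["f_so_dist"].total_N == pytest.approx(1.3, abs=1e-12)
        assert out["f_lgpl_prox"].passive_N == pytest.approx(
            noiseless_spec.passive_lgpl_N, abs=1e-12
        )

    def test_twitch_in_window_shifts_with_warning(self):
        # A late twitch bump sits inside the nominal passive window.
        def profile(t):
            f = np.where(t >= 2.0, 5.0, 1.0)
            f[(t >= 1.97) & (t < 1.99)] = 3.0
            return f

        wf = _waveform(profile, twitches=(0.5, 1.97))
        with pytest.warns(UserWarning, match="shifting window"):
            out = extract_isometric(wf)
        assert out["f_so_dist"].passive_N == pytest.approx(1.0, abs=1e-12)

    def test_window_longer_than_stimulation(self):
        wf = _waveform(lambda t: np.where(t >= 2.0, 5.0, 1.0), stim_offset=2.02)
        with pytest.raises(ExtractionError):
            extract_isometric(wf, window_ms=50.0)


class TestForceDifferences:
    def _table(self, spec):
        return generate_calibration_dataset(spec)[0]

    def test_delta_lgpl_is_proximal_minus_distal(self, noiseless_spec):
        t = self._table(noiseless_spec)
        d = delta_F_LGPL(t)
        expected = (
            t.channel("f_lgpl_prox").to_numpy() - t.channel("f_lgpl_dist").to_numpy()
        )
        assert np.allclose(d.to_numpy(), expected, atol=1e-15)

    def test_delta_so_zero_at_reference(self, noiseless_spec):
        t = self._table(noiseless_spec)
        assert delta_F_SO(t).loc[0.0] == 0.0

    def test_delta_so_relative_values(self):
        spec_like = pd.Series([1.0, 1.3, 1.6], index=[-1.0, 0.0, 1.0])
        # subtraction relative to the reference entry
        rel = spec_like - spec_like.loc[0.0]
        assert list(rel) == pytest.approx([-0.3, 0.0, 0.3])


class TestPathwayEstimator:
    def test_direct_substitution(self):
        est = estimate_pathway_forces(
            [0.6], [0.15], [0.10], c=0.9, positions_mm=[1.0]
        )
        assert est.f_int_N[0] == pytest.approx(0.455, abs=1e-12)
        assert est.f_nv1_N[0] == pytest.approx(0.05, abs=1e-12)
        assert est.f_nv2_N[0] == pytest.approx(0.10, abs=1e-12)

    def test_c_equal_one_limit(self):
        est = estimate_pathway_forces(
            [0.6, 0.2], [0.15, 0.1], [0.10, 0.05], c=1.0, positions_mm=[0.0, 1.0]
        )
        assert np.allclose(est.f_int_N, np.array([0.6, 0.2]) - np.array([0.15, 0.1]))

    def test_all_zero_inputs(self):
        est = estimate_pathway_forces(
            np.zeros(7), np.zeros(7), np.zeros(7), positions_mm=POSITIONS
        )
        assert not est.f_int_N.any() and not est.f_nv1_N.any()

    @given(di=series3, d1=series3, d2=series3, c=st.floats(0.05, 1.0))
    @settings(derandomize=True, max_examples=100)
    def test_conservation_identity(self, di, d1, d2, c):
        """F_INT + F_NV1 + F_NV2 - (1-c) F_NV1 == dF_intact, exactly."""
        est = estimate_pathway_forces(di, d1, d2, c=c, positions_mm=POSITIONS)
        lhs = est.f_int_N + est.f_nv1_N + est.f_nv2_N - (1.0 - c) * est.f_nv1_N
        assert np.allclose(lhs, np.asarray(di), rtol=0.0, atol=1e-12)

    def test_linearity_superposition(self):
        rng = np.random.default_rng(0)
        a = [rng.normal(size=7) for _ in range(3)]
        b = [rng.normal(size=7) for _ in range(3)]
        est_sum = estimate_pathway_forces(
            *(x + y for x, y in zip(a, b)), c=0.7, positions_mm=POSITIONS
        )
        est_a = estimate_pathway_forces(*a, c=0.7, positions_mm=POSITIONS)
        est_b = estimate_pathway_forces(*b, c=0.7, positions_mm=POSITIONS)
        for name in ("INT", "NV1", "NV2"):
            assert np.allclose(
                est_sum.pathway(name),
                est_a.pathway(name) + est_b.pathway(name),
                atol=1e-12,
            )

    def test_invalid_c(self):
        with pytest.raises(ParameterError):
            estimate_pathway_forces([0.1], [0.1], [0.1], c=1.2, positions_mm=[0.0])

    def test_length_mismatch(self):
        with pytest.raises(StructuralError):
            estimate_pathway_forces([0.1, 0.2], [0.1], [0.1], positions_mm=[0.0, 1.0])


def _estimates_from_profile(f_of_p, positions=POSITIONS):
    vals = np.array([f_of_p(p) for p in positions])
    return PathwayForceEstimates(
        positions_mm=positions,
        f_int_N=vals,
        f_nv1_N=np.zeros_like(vals),
        f_nv2_N=np.zeros_like(vals),
        c=0.9,
        group="NO",
    )


class TestStiffnessFit:
    def test_table_round_trip_control_int(self):
        # Force profile whose increments are the control INT stiffnesses.
        cum = {0.0: 0.0, 1.0: 0.2398, 2.0: 0.4115, 3.0: 0.5554}
        est = _estimates_from_profile(
            lambda p: np.sign(p) * cum[abs(p)]
        )
        sset = fit_piecewise_stiffness(est)
        assert sset.pathways["INT"].values_mN_per_mm == pytest.approx(
            (239.8, 171.7, 143.9), abs=1e-9
        )

    def test_linear_force_gives_constant_stiffness(self):
        est = _estimates_from_profile(lambda p: 0.1 * p)
        sset = fit_piecewise_stiffness(est)
        assert sset.pathways["INT"].values == pytest.approx((0.1, 0.1, 0.1))

    def test_symmetry_averaging_of_mirrored_slopes(self):
        # +200 mN/mm on the positive side, 220 mN/mm mirrored -> mean 210.
        def profile(p):
            return 0.200 * p if p >= 0 else 0.220 * p

        est = _estimates_from_profile(profile)
        sset = fit_piecewise_stiffness(est, symmetry=True)
        assert sset.pathways["INT"].values_mN_per_mm[0] == pytest.approx(210.0)
        asym = fit_piecewise_stiffness(est, symmetry=False)
        assert asym.pathways["INT"].values_mN_per_mm[0] == pytest.approx(200.0)
        assert asym.pathways["INT"].negative_values[0] == pytest.approx(0.220)

    def test_missing_position_is_structural_error(self):
        est = _estimates_from_profile(lambda p: 0.1 * p, positions=POSITIONS[1:])
        with pytest.raises(StructuralError):
            fit_piecewise_stiffness(est)


class TestCSensitivity:
    def test_matches_closed_form(self):
        rng = np.random.default_rng(3)
        di, d1, d2 = (rng.normal(size=7) for _ in range(3))
        curve = c_sensitivity(di, d1, d2, positions_mm=POSITIONS)
        ref = estimate_pathway_forces(di, d1, d2, c=0.9, positions_mm=POSITIONS)
        rms_nv1 = np.sqrt(np.mean(ref.f_nv1_N**2))
        denom = np.mean(np.abs(ref.f_int_N))
        for c, val in curve.items():
            closed = 100.0 * abs(c - 0.9) * rms_nv1 / denom
            assert val == pytest.approx(closed, abs=1e-9)

    def test_zero_when_post_conditions_agree(self):
        d = np.linspace(-0.5, 0.5, 7)
        curve = c_sensitivity(d, d * 0.3, d * 0.3, positions_mm=POSITIONS)
        assert np.allclose(curve.to_numpy(), 0.0, atol=1e-12)

    def test_zero_at_reference_c(self):
        rng = np.random.default_rng(4)
        di, d1, d2 = (rng.normal(size=7) for _ in range(3))
        curve = c_sensitivity(di, d1, d2, c_grid=[0.9], positions_mm=POSITIONS)
        assert curve.loc[0.9] == pytest.approx(0.0, abs=1e-12)

    def test_undefined_when_reference_force_vanishes(self):
        z = np.zeros(7)
        with pytest.raises(ParameterError):
            c_sensitivity(z, z, z, positions_mm=POSITIONS)


class TestScaleFactor:
    def test_round_trip(self):
        full = PiecewiseStiffness(pathway="INT", values=(0.2398, 0.1717, 0.1439))
        prox = PiecewiseStiffness(
            pathway="INT",
            values=tuple(
                k * f for k, f in zip(full.values, (0.07, 0.13, 0.21))
            ),
        )
        assert estimate_r(full, prox) == pytest.approx((0.07, 0.13, 0.21))

    def test_identical_inputs_give_unity(self):
        full = PiecewiseStiffness(pathway="INT", values=(0.1, 0.2, 0.3))
        assert estimate_r(full, full) == pytest.approx((1.0, 1.0, 1.0))

    def test_zero_denominator(self):
        full = PiecewiseStiffness(pathway="INT", values=(0.0, 0.2, 0.3))
        with pytest.raises(ParameterError):
            estimate_r(full, full)


class TestPathwayRatios:
    def test_simple_percentage(self):
        est = _estimates_from_profile(lambda p: 1.15 if p == 1.0 else 0.0)
        ratios = pathway_ratios(est, 11.5)
        assert ratios.loc[1.0, "INT"] == pytest.approx(10.0)
        assert ratios.loc[0.0, "net"] == pytest.approx(0.0)

    def test_requires_positive_denominator(self):
        est = _estimates_from_profile(lambda p: 0.1 * p)
        with pytest.raises(ParameterError):
            pathway_ratios(est, 0.0)


class TestGroupCalibration:
    def test_passive_estimation_refused_by_default(self, noiseless_spec):
        tables = generate_calibration_dataset(noiseless_spec)
        with pytest.raises(ParameterError):
            calibrate_group(tables, state="passive")

    def test_passive_override_warns(self, noiseless_spec):
        tables = generate_calibration_dataset(noiseless_spec)
        with pytest.warns(UserWarning, match="passive"):
            calibrate_group(tables, state="passive", allow_passive=True)

    def test_recovered_k1_spread_shrinks_with_group_size(self, control_set):
        """SD of the recovered K1 scales as 1/sqrt(n) across animals."""
        sds = {}
        for n in (1, 4):
            k1 = []
            for rep in range(200):
                spec = SyntheticSpec(
                    truth=control_set,
                    n_animals=n,
                    noise_sd_N=0.05,
                    seed=1000 * n + rep,
                )
                cal = calibrate_group(generate_calibration_dataset(spec))
                k1.append(cal.stiffness.pathways["INT"].values[0])
            sds[n] = np.std(k1, ddof=1)
        ratio = sds[1] / sds[4]
        assert ratio == pytest.approx(2.0, rel=0.35)
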