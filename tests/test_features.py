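"""Asymmetry indices, harmonic features and retraction asymmetry: formula
checks against hand computation and the brute-force landmark oracle, plus the
null, mirror and scale-invariance properties."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import equigait as eg
from equigait.features import ASI_KEYS, FEATURE_NAMES, FourierFeatures, wrap_phase_deg
from equigait.processing import N_POINTS, StrideLandmarks

from .oracles import brute_force_landmarks

GRID = np.linspace(0.0, 1.0, N_POINTS)


def make_landmarks(**kw) -> StrideLandmarks:
    base = dict(
        min_R=-1.0, min_L=-1.0, max_R=1.0, max_L=1.0,
        up_R=2.0, up_L=2.0, down_R=2.0, down_L=2.0,
        diffTmax_R=2.0, diffTmax_L=2.0, ROM=2.0, reference_side="forelimb",
    )
    base.update(kw)
    return StrideLandmarks(**base)


class TestAsymmetryIndices:
    @pytest.mark.parametrize("dialect", ["caption", "rom_normalized"])
    def test_symmetric_landmarks_give_zero(self, dialect):
        asi = eg.asymmetry_indices(make_landmarks(), dialect=dialect)
        assert all(v == 0.0 for v in asi.values())

    def test_caption_formulas_match_hand_computation_from_oracle(self):
        """The five caption-dialect formulas applied by hand to brute-force
        landmark values of -cos(4 pi u) + 0.2 sin(2 pi u)."""
        func = lambda u: -np.cos(4 * np.pi * u) + 0.2 * np.sin(2 * np.pi * u)
        ora = brute_force_landmarks(func, phase_R=0.75, phase_L=0.25)
        lm = eg.curve_landmarks(func(GRID), phase_R=0.75, phase_L=0.25)
        asi = eg.asymmetry_indices(lm, dialect="caption")
        expected = {
            "AsI-min": 100 * (ora["min_R"] - ora["min_L"]) / ora["up_L"],
            "AsI-max": 100 * (ora["max_L"] - ora["max_R"]) / ora["up_L"],
            "AsI-up": 100 * (ora["up_L"] - ora["up_R"]) / ora["up_L"],
            "AsI-down": 100 * (ora["down_L"] - ora["down_R"]) / ora["down_L"],
            "AsI-Tmax": 100 * (ora["diffTmax_L"] - ora["diffTmax_R"]) / ora["diffTmax_L"],
        }
        for key in ASI_KEYS:
            assert asi[key] == pytest.approx(expected[key], abs=1e-9), key

    def test_rom_dialect_uses_rom_denominator(self):
        lm = make_landmarks(up_R=1.5, ROM=4.0)
        asi = eg.asymmetry_indices(lm, dialect="rom_normalized")
        assert asi["AsI-up"] == pytest.approx(100 * (2.0 - 1.5) / 4.0)
        caption = eg.asymmetry_indices(lm, dialect="caption")
        assert caption["AsI-up"] == pytest.approx(100 * (2.0 - 1.5) / 2.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_rom_dialect_antisymmetry_property(self, data):
        """Mirroring landmarks negates every ROM-normalized index exactly."""
        vals = {
            k: data.draw(st.floats(0.1, 3.0), label=k)
            for k in ("up_R", "up_L", "down_R", "down_L", "diffTmax_R", "diffTmax_L")
        }
        lm = make_landmarks(
            min_R=data.draw(st.floats(-2, -0.5)), min_L=data.draw(st.floats(-2, -0.5)),
            max_R=data.draw(st.floats(0.5, 2)), max_L=data.draw(st.floats(0.5, 2)),
            ROM=4.0, **vals,
        )
        asi = eg.asymmetry_indices(lm, dialect="rom_normalized")
        mirrored = eg.asymmetry_indices(lm.swapped(), dialect="rom_normalized")
        for key in ASI_KEYS:
            assert mirrored[key] == -asi[key]

    def test_zero_denominator_names_the_index(self):
        with pytest.raises(eg.DegenerateLandmarksError, match="AsI-down"):
            eg.asymmetry_indices(make_landmarks(down_L=0.0), dialect="caption")
        with pytest.raises(eg.DegenerateLandmarksError, match="AsI-up"):
            eg.asymmetry_indices(make_landmarks(ROM=0.0, up_L=0.0), dialect="rom_normalized")


class TestHarmonicFit:
    def test_pure_second_harmonic(self):
        fit = eg.harmonic_fit(2 * np.cos(4 * np.pi * GRID))
        assert fit.amplitude_2 == pytest.approx(2.0, abs=1e-12)
        assert fit.amplitude_1 == pytest.approx(0.0, abs=1e-12)

    def test_mixed_harmonics_amplitudes_and_phases(self):
        fit = eg.harmonic_fit(np.sin(2 * np.pi * GRID) + 2 * np.cos(4 * np.pi * GRID))
        assert fit.amplitude_1 == pytest.approx(1.0, abs=1e-12)
        assert fit.amplitude_2 == pytest.approx(2.0, abs=1e-12)
        assert fit.phase_1 == pytest.approx(90.0, abs=1e-9)
        assert fit.phase_2 == pytest.approx(0.0, abs=1e-9)
        assert fit.residual_rms == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_is_absorbed(self):
        curve = np.sin(2 * np.pi * GRID) + 2 * np.cos(4 * np.pi * GRID)
        a = eg.harmonic_fit(curve)
        b = eg.harmonic_fit(curve + 5.0)
        for x, y in ((a.amplitude_1, b.amplitude_1), (a.amplitude_2, b.amplitude_2),
                     (a.phase_1, b.phase_1), (a.phase_2, b.phase_2)):
            assert x == pytest.approx(y, abs=1e-9)

    def test_constant_curve_has_zero_amplitudes_and_phases(self):
        fit = eg.harmonic_fit(np.full(101, 3.7))
        assert fit.amplitude_1 == pytest.approx(0.0, abs=1e-12)
        assert fit.amplitude_2 == pytest.approx(0.0, abs=1e-12)
        assert fit.phase_1 == 0.0 and fit.phase_2 == 0.0


class TestFourierFeatures:
    def test_equal_amplitudes_give_100(self):
        fit = eg.HarmonicFit(1.0, 1.0, 0.0, 0.0, 0.0)
        assert eg.fourier_features(fit).erz == pytest.approx(100.0)

    def test_hand_computed_energy_ratio_and_phase(self):
        fit = eg.HarmonicFit(amplitude_1=1.0, amplitude_2=2.0, phase_1=90.0,
                             phase_2=0.0, residual_rms=0.0)
        ff = eg.fourier_features(fit)
        assert ff.erz == pytest.approx(400.0)
        assert ff.dphi == pytest.approx(90.0)
        assert not ff.degenerate

    def test_degenerate_first_harmonic_is_capped_and_flagged(self):
        ff = eg.fourier_features(eg.HarmonicFit(0.0, 2.0, 0.0, 0.0, 0.0))
        assert ff.erz == 1e6 and ff.degenerate
        tiny = eg.fourier_features(eg.HarmonicFit(1e-9, 2.0, 0.0, 0.0, 0.0), erz_ceiling=1e4)
        assert tiny.erz == 1e4 and tiny.degenerate

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-1000, 1000))
    def test_wrap_phase_range(self, x):
        y = wrap_phase_deg(x)
        assert -180.0 < y <= 180.0
        assert (y - x) % 360.0 == pytest.approx(0.0, abs=1e-9) or (y - x) % 360.0 == pytest.approx(360.0, abs=1e-9)


class TestRetraction:
    def test_direct_arithmetic_on_definition(self, zero_noise_params):
        """left 20 deg, right 16 deg -> 100 * 4 / 18 = 22.22%."""
        # grade chosen so the simulated RF amplitude is exactly 16 while LF
        # stays at 20: deficit 0.04/grade * 5 = 0.2
        params = dataclasses.replace(
            zero_noise_params, retraction_amplitude=20.0, retraction_deficit_per_grade=0.04
        )
        trial = eg.simulate_trial("RF", 5, params)
        idx = eg.retraction_asymmetry(trial, "fore")
        assert idx == pytest.approx(100 * 4 / 18, rel=1e-4)

    def test_equal_sides_give_zero(self, zero_noise_params):
        trial = eg.simulate_trial("SOUND", 0, zero_noise_params)
        assert eg.retraction_asymmetry(trial, "fore") == pytest.approx(0.0, abs=1e-5)
        assert eg.retraction_asymmetry(trial, "hind") == pytest.approx(0.0, abs=1e-5)

    def test_rf_lame_gives_positive_fore_index(self, zero_noise_params):
        """A right-forelimb deficit reduces the right retraction, so
        left > right and the fore index is positive."""
        trial = eg.simulate_trial("RF", 4, zero_noise_params)
        assert eg.retraction_asymmetry(trial, "fore") > 1.0
        assert eg.retraction_asymmetry(trial, "hind") == pytest.approx(0.0, abs=1e-5)

    def test_missing_liftoff_events_raise(self, zero_noise_params):
        trial = eg.simulate_trial("RF", 4, zero_noise_params)
        trial.stance_events["LF"] = trial.stance_events["LF"][:2]
        with pytest.raises(eg.FeatureExtractionError, match="lift-off"):
            eg.retraction_asymmetry(trial, "fore")

    def test_unknown_pair_rejected(self, zero_noise_params):
        trial = eg.simulate_trial("RF", 4, zero_noise_params)
        with pytest.raises(ValueError, match="pair"):
            eg.retraction_asymmetry(trial, "left")


class TestFeatureVector:
    def test_27_finite_named_features(self, small_cohort):
        fv = eg.build_feature_vector(small_cohort[0])
        assert tuple(fv) == FEATURE_NAMES
        assert len(fv) == 27
        assert all(np.isfinite(v) for v in fv.values())

    def test_zero_noise_sound_trial_null(self, zero_noise_params):
        """Noise-free sound trot: every asymmetry and retraction feature is
        zero (to the interpolation floor) and ERz hits the degenerate cap."""
        fv = eg.build_feature_vector(eg.simulate_trial("SOUND", 0, zero_noise_params))
        for name, value in fv.items():
            if name.startswith("AsI"):
                assert abs(value) < 1e-5, name
        for sensor in eg.SENSORS:
            assert fv[f"ERz_{sensor}"] == 1e6  # capped: no first harmonic

    def test_determinism(self, zero_noise_params):
        params = dataclasses.replace(zero_noise_params, noise_sd=0.05, angle_noise_sd=0.2)
        a = eg.build_feature_vector(eg.simulate_trial("LH", 3, params))
        b = eg.build_feature_vector(eg.simulate_trial("LH", 3, params))
        assert a == b

    def test_mirror_property(self, zero_noise_params):
        """Mirroring a trial negates AsI and retraction features in the ROM
        dialect, preserves ERz/ROM/stride frequency, and shifts dphi by 180
        deg (the stride start moves half a stride with the reference limb)."""
        trial = eg.simulate_trial("RF", 4, zero_noise_params)
        fv = eg.build_feature_vector(trial, dialect="rom_normalized")
        fm = eg.build_feature_vector(eg.mirror_trial(trial), dialect="rom_normalized")
        for name in FEATURE_NAMES:
            if name.startswith("AsI"):
                assert fm[name] == pytest.approx(-fv[name], abs=1e-6), name
            elif name.startswith("dphi"):
                assert fm[name] == pytest.approx(
                    wrap_phase_deg(fv[name] + 180.0), abs=1e-5
                ), name
            elif name.startswith("ERz"):
                assert fm[name] == pytest.approx(fv[name], rel=1e-5), name
            else:  # ROM, stride_frequency
                assert fm[name] == pytest.approx(fv[name], rel=1e-8), name

    def test_noiseless_erz_matches_generator_closed_form(self, zero_noise_params):
        """On the two-harmonic model, ERz = 100 * (A_s / a_s)^2 exactly in
        the noiseless limit."""
        grade = 4
        trial = eg.simulate_trial("RH", grade, zero_noise_params)
        fv = eg.build_feature_vector(trial)
        p = zero_noise_params
        for j, sensor in enumerate(eg.SENSORS):
            ratio = abs(p.asymmetry_gain * grade * p.compensation_matrix["RH"][j])
            assert fv[f"ERz_{sensor}"] == pytest.approx(100.0 / ratio**2, rel=1e-4)

    def test_scale_invariance(self, zero_noise_params):
        """Scaling displacement by k scales ROM by k and leaves AsI (%) and
        ERz unchanged."""
        trial = eg.simulate_trial("LF", 5, zero_noise_params)
        fv = eg.build_feature_vector(trial)
        scaled = dataclasses.replace(trial)
        scaled.displacement = {s: 2.5 * v for s, v in trial.displacement.items()}
        fs = eg.build_feature_vector(scaled)
        for name in FEATURE_NAMES:
            if name.startswith("ROM"):
                assert fs[name] == pytest.approx(2.5 * fv[name], rel=1e-9)
            elif name.startswith(("AsI", "ERz", "dphi")) or name == "stride_frequency":
                assert fs[name] == pytest.approx(fv[name], rel=1e-6), name

    def test_grade_monotonicity(self, zero_noise_params):
        """Asymmetry magnitude grows with grade at fixed seed, zero noise."""
        mags = []
        for grade in (0, 2, 4, 6):
            label = "SOUND" if grade == 0 else "RF"
            fv = eg.build_feature_vector(eg.simulate_trial(label, grade, zero_noise_params))
            mags.append(abs(fv["AsI-up_H"]))
        assert all(a <= b + 1e-9 for a, b in zip(mags, mags[1:]))

    def test_error_carries_trial_id(self, zero_noise_params):
        short = dataclasses.replace(zero_noise_params, n_strides=3)
        trial = eg.simulate_trial("SOUND", 0, short, trial_id="horse42")
        trial.stance_events = {l: ev[:3] for l, ev in trial.stance_events.items()}
        with pytest.raises(eg.FeatureExtractionError, match="horse42"):
            eg.build_feature_vector(trial)

    def test_feature_table_round_trip(self, tmp_path, small_cohort):
        table = eg.cohort_feature_table(small_cohort[:6])
        path = tmp_path / "features.csv"
        eg.write_feature_table(table, path)
        back = eg.read_feature_table(path)
        assert list(back.columns) == list(table.columns)
        for name in FEATURE_NAMES:
            np.testing.assert_allclose(back[name], table[name], rtol=0, atol=0)
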