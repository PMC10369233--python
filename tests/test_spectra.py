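"""Reference spectra, GC-MS weighting and chain-length calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import simpson

from srsfa.errors import (
    AugmentationDegenerateError,
    AxisMismatchError,
    CalibrationError,
    DegenerateWeightsError,
    InvalidSpectrumError,
    ValidationError,
)
from srsfa.spectra import (
    CH2_WINDOW,
    CH3_WINDOW,
    ChainLengthCalibration,
    GCMSProfile,
    ReferenceLibrary,
    Spectrum,
    WavenumberAxis,
    ch2_ch3_auc_ratio,
    composite_unsaturated_reference,
    fit_chain_length_calibration,
    normalize_spectrum,
    parse_species,
    predict_chain_length,
    scale_references_by_gcms,
)
from srsfa.synthetic import make_reference_spectra, model_spectrum


def fine_grid_integral(s: Spectrum, lo: float, hi: float, n: int = 20001) -> float:
    """Independent integration oracle: dense linear interpolation + Simpson."""
    x = np.linspace(lo, hi, n)
    y = np.interp(x, s.axis.values, s.intensity)
    return float(simpson(y, x=x))


class TestWavenumberAxis:
    def test_rejects_non_monotone_and_negative(self):
        with pytest.raises(ValueError):
            WavenumberAxis(np.array([2900.0, 2850.0, 2950.0]))
        with pytest.raises(ValueError):
            WavenumberAxis(np.array([-1.0, 2850.0]))

    def test_window_weights_match_fine_grid_oracle(self):
        axis = WavenumberAxis(np.linspace(2800, 3050, 40))
        rng = np.random.default_rng(7)
        y = rng.uniform(0.5, 2.0, 40)
        s = Spectrum(axis, y)
        for lo, hi in (CH2_WINDOW, CH3_WINDOW, (2815.3, 3011.7)):
            w = axis.window_weights(lo, hi)
            assert w @ y == pytest.approx(fine_grid_integral(s, lo, hi), rel=1e-6)

    def test_window_outside_span_rejected(self):
        axis = WavenumberAxis(np.linspace(2900, 2950, 10))
        with pytest.raises(ValueError):
            axis.window_weights(2832, 2888)


class TestNormalizeSpectrum:
    def test_boxcar_height_forced_to_reciprocal_span(self, boxcar):
        out = normalize_spectrum(boxcar)
        np.testing.assert_allclose(out.intensity, 1.0 / 250.0)

    def test_idempotent_on_unit_area_input(self, boxcar):
        once = normalize_spectrum(boxcar)
        twice = normalize_spectrum(once)
        np.testing.assert_array_equal(once.intensity, twice.intensity)

    def test_model_spectrum_area_matches_integration_oracle(self):
        s = normalize_spectrum(model_spectrum("C16:0"))
        lo, hi = s.axis.span
        assert fine_grid_integral(s, lo, hi) == pytest.approx(1.0, abs=1e-6)
        assert s.area() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_rejected(self, toy_axis):
        with pytest.raises(InvalidSpectrumError):
            normalize_spectrum(Spectrum(toy_axis, np.zeros(6)))

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.01, 100.0), min_size=6, max_size=6))
    def test_idempotence_property(self, values):
        axis = WavenumberAxis(np.linspace(2800.0, 3050.0, 6))
        once = normalize_spectrum(Spectrum(axis, np.array(values)))
        assert once.area() == pytest.approx(1.0, abs=1e-9)
        twice = normalize_spectrum(once)
        np.testing.assert_allclose(twice.intensity, once.intensity, rtol=1e-12)


class TestCompositeUnsaturated:
    def test_single_nonzero_weight_returns_that_spectrum(self, toy_axis):
        a = Spectrum(toy_axis, np.array([1, 2, 3, 4, 5, 6.0]))
        b = Spectrum(toy_axis, np.array([6, 5, 4, 3, 2, 1.0]))
        out = composite_unsaturated_reference([a, b], [1.0, 0.0])
        np.testing.assert_allclose(out.intensity, normalize_spectrum(a).intensity)

    def test_equal_weights_identical_spectra_unchanged(self, toy_axis):
        a = Spectrum(toy_axis, np.array([1, 2, 3, 4, 5, 6.0]))
        out = composite_unsaturated_reference([a, a, a], [1, 1, 1])
        np.testing.assert_allclose(out.intensity, normalize_spectrum(a).intensity)

    def test_weighted_sum_matches_pointwise_oracle(self, toy_axis):
        a = Spectrum(toy_axis, np.array([1, 2, 3, 4, 5, 6.0]))
        b = Spectrum(toy_axis, np.array([2, 2, 8, 1, 1, 2.0]))
        out = composite_unsaturated_reference([a, b], [0.25, 0.75])
        na, nb = normalize_spectrum(a).intensity, normalize_spectrum(b).intensity
        expected = 0.25 * na + 0.75 * nb  # independent pointwise oracle
        np.testing.assert_allclose(out.intensity, expected, atol=1e-12)

    def test_output_within_input_envelope(self, toy_axis):
        a = normalize_spectrum(Spectrum(toy_axis, np.array([1, 2, 3, 4, 5, 6.0])))
        b = normalize_spectrum(Spectrum(toy_axis, np.array([2, 2, 8, 1, 1, 2.0])))
        out = composite_unsaturated_reference([a, b], [0.3, 0.7])
        lo = np.minimum(a.intensity, b.intensity)
        hi = np.maximum(a.intensity, b.intensity)
        assert np.all(out.intensity >= lo - 1e-12)
        assert np.all(out.intensity <= hi + 1e-12)

    def test_errors(self, toy_axis):
        a = Spectrum(toy_axis, np.ones(6))
        other = Spectrum(WavenumberAxis(np.linspace(2810, 3040, 6)), np.ones(6))
        with pytest.raises(AxisMismatchError):
            composite_unsaturated_reference([a, other], [1, 1])
        with pytest.raises(DegenerateWeightsError):
            composite_unsaturated_reference([a, a], [0.0, 0.0])


class TestGCMSProfile:
    def test_species_validation(self):
        with pytest.raises(ValidationError):
            parse_species("C15:0")  # odd chain
        with pytest.raises(ValidationError):
            parse_species("C16:2")  # polyunsaturated
        with pytest.raises(ValidationError):
            GCMSProfile({"C14:0": 0.0})  # no positive entry

    def test_saturated_fractions_sum_to_one(self):
        p = GCMSProfile({"C8:0": 30.0, "C14:0": 60.0, "C16:1": 10.0})
        fracs = p.saturated_fractions()
        assert sum(fracs.values()) == pytest.approx(1.0)
        assert fracs[8] == pytest.approx(1.0 / 3.0)


class TestScaleReferencesByGcms:
    def test_share_arithmetic_matches_hand_summed_oracle(self):
        lib = make_reference_spectra(["protein", "C8:0", "C14:0", "unsat"]).normalized()
        profile = GCMSProfile({"C8:0": 30.0, "C14:0": 60.0, "C16:1": 10.0})
        scaled = scale_references_by_gcms(lib, profile)
        # hand-summed shares: 30/100, 60/100, 10/100 on (C8:0, C14:0, unsat)
        assert scaled["C8:0"].spectrum.area() == pytest.approx(0.3)
        assert scaled["C14:0"].spectrum.area() == pytest.approx(0.6)
        assert scaled["unsat"].spectrum.area() == pytest.approx(0.1)

    def test_equal_concentrations_give_equal_constants(self):
        lib = make_reference_spectra(["C8:0", "C10:0", "C12:0"]).normalized()
        profile = GCMSProfile({"C8:0": 5.0, "C10:0": 5.0, "C12:0": 5.0})
        scaled = scale_references_by_gcms(lib, profile)
        areas = [c.spectrum.area() for c in scaled.components]
        np.testing.assert_allclose(areas, 1.0 / 3.0)

    def test_zero_concentration_species_kept_inert(self):
        lib = make_reference_spectra(["C14:0", "C18:0"]).normalized()
        profile = GCMSProfile({"C14:0": 10.0, "C18:0": 0.0})
        scaled = scale_references_by_gcms(lib, profile)
        assert len(scaled) == len(lib)
        np.testing.assert_array_equal(scaled["C18:0"].spectrum.intensity, 0.0)

    def test_protein_bit_identical_and_component_count_preserved(self, norm_library):
        profile = GCMSProfile({"C8:0": 1.0, "C10:0": 2.0, "C12:0": 1.0,
                               "C14:0": 3.0, "C16:0": 1.0, "C18:0": 1.0,
                               "C16:1": 1.0})
        scaled = scale_references_by_gcms(norm_library, profile)
        assert scaled.names == norm_library.names
        np.testing.assert_array_equal(
            scaled["protein"].spectrum.intensity,
            norm_library["protein"].spectrum.intensity,
        )

    def test_orphan_profile_species_warns_and_renormalizes(self):
        lib = make_reference_spectra(["C8:0", "C14:0"]).normalized()
        profile = GCMSProfile({"C8:0": 25.0, "C14:0": 25.0, "C20:0": 50.0})
        with pytest.warns(UserWarning, match="absent from library"):
            scaled = scale_references_by_gcms(lib, profile)
        assert scaled["C8:0"].spectrum.area() == pytest.approx(0.5)

    def test_all_zero_shares_rejected(self):
        lib = make_reference_spectra(["C8:0"]).normalized()
        with pytest.raises(AugmentationDegenerateError):
            with pytest.warns(UserWarning):
                scale_references_by_gcms(lib, GCMSProfile({"C10:0": 1.0}))


class TestAucRatio:
    def test_constant_spectrum_gives_window_length_ratio(self):
        axis = WavenumberAxis(np.linspace(2800, 3050, 40))
        s = Spectrum(axis, np.full(40, 2.5))
        assert ch2_ch3_auc_ratio(s) == pytest.approx(56.0 / 58.0, rel=1e-12)

    def test_global_scaling_leaves_ratio_unchanged(self):
        s = model_spectrum("C12:0")
        scaled = Spectrum(s.axis, s.intensity * 10.0)
        assert ch2_ch3_auc_ratio(scaled) == pytest.approx(
            ch2_ch3_auc_ratio(s), rel=1e-12
        )

    def test_matches_fine_grid_integration_oracle(self):
        s = model_spectrum("C16:0")
        oracle = fine_grid_integral(s, *CH2_WINDOW) / fine_grid_integral(s, *CH3_WINDOW)
        assert ch2_ch3_auc_ratio(s) == pytest.approx(oracle, rel=1e-6)

    def test_zero_ch3_area_returns_nan(self, toy_axis):
        s = Spectrum(toy_axis, np.zeros(6))
        assert np.isnan(ch2_ch3_auc_ratio(s))

    def test_strictly_increasing_over_saturated_series(self, standards_library):
        ratios = [
            ch2_ch3_auc_ratio(c.spectrum) for c in standards_library.saturated()
        ]
        assert all(b > a for a, b in zip(ratios, ratios[1:]))


class TestCalibration:
    def test_exactly_linear_ratios_fit_perfectly(self, toy_axis):
        # synthesize spectra whose AUC ratio is exactly linear in n by
        # mixing two fixed shapes with known window areas
        base = np.array([0.0, 1.0, 0.0, 0.0, 0.0, 0.0])
        tail = np.array([0.0, 0.0, 0.0, 1.0, 0.0, 0.0])
        axis = WavenumberAxis(np.linspace(2800, 3050, 6))
        standards = []
        for n in (8, 12, 16, 20):
            standards.append((n, Spectrum(axis, n * base + 7.0 * tail)))
        cal = fit_chain_length_calibration(standards)
        assert cal.r_squared == pytest.approx(1.0, abs=1e-12)
        for n, s in standards:
            assert predict_chain_length(ch2_ch3_auc_ratio(s), cal) == pytest.approx(n)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        ns, ratios, spectra = [], [], []
        axis = WavenumberAxis(np.linspace(2800, 3050, 40))
        for n in (6, 10, 12, 16, 20):
            s = model_spectrum(f"C{n}:0", axis=axis)
            noisy = Spectrum(axis, s.intensity + rng.normal(0, 0.05, 40))
            spectra.append((n, noisy))
            ns.append(float(n))
            ratios.append(ch2_ch3_auc_ratio(noisy))
        cal = fit_chain_length_calibration(spectra)
        # closed-form normal equations oracle
        x, y = np.asarray(ratios), np.asarray(ns)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        intercept = y.mean() - slope * x.mean()
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert cal.slope == pytest.approx(slope, abs=1e-10)
        assert cal.intercept == pytest.approx(intercept, abs=1e-10)
        assert cal.r_squared == pytest.approx(r2, abs=1e-10)

    def test_noiseless_standards_predict_within_quarter_carbon(
        self, standards_library, calibration
    ):
        for c in standards_library.saturated():
            pred = predict_chain_length(ch2_ch3_auc_ratio(c.spectrum), calibration)
            assert pred == pytest.approx(c.chain_length, abs=0.25)

    def test_underdetermined_inputs_rejected(self, toy_axis):
        s = Spectrum(toy_axis, np.ones(6))
        with pytest.raises(CalibrationError):
            fit_chain_length_calibration([(8, s), (10, s)])
        with pytest.raises(CalibrationError):
            fit_chain_length_calibration([(8, s), (10, s), (12, s)])

    def test_windows_must_not_overlap(self):
        with pytest.raises(CalibrationError):
            ChainLengthCalibration(
                slope=1.0, intercept=0.0, r_squared=1.0,
                ch2_window=(2832, 2920), ch3_window=(2909, 2967),
            )


class TestPredictChainLength:
    def test_linear_arithmetic(self, calibration):
        cal = ChainLengthCalibration(slope=2.0, intercept=4.0, r_squared=1.0)
        assert predict_chain_length(5.0, cal) == pytest.approx(14.0)

    def test_clipped_to_standards_range(self):
        cal = ChainLengthCalibration(slope=2.0, intercept=4.0, r_squared=1.0)
        assert predict_chain_length(100.0, cal) == 20.0
        assert predict_chain_length(-100.0, cal) == 6.0
        assert predict_chain_length(100.0, cal, clip=False) == pytest.approx(204.0)

    def test_synthetic_c12_round_trip(self):
        from srsfa.synthetic import noisy_standards

        standards = noisy_standards(
            [f"C{n}:0" for n in range(6, 21, 2)], snr=20, n_replicates=6, seed=2
        )
        cal = fit_chain_length_calibration(standards)
        ratio = ch2_ch3_auc_ratio(model_spectrum("C12:0"))
        assert predict_chain_length(ratio, cal) == pytest.approx(12.0, abs=0.5)


class TestLibraryValidation:
    def test_duplicate_names_rejected(self, toy_axis):
        from srsfa.spectra import Component

        s = Spectrum(toy_axis, np.ones(6))
        with pytest.raises(ValueError):
            ReferenceLibrary(
                (
                    Component("C8:0", "saturated", s, chain_length=8),
                    Component("C8:0", "saturated", s, chain_length=8),
                )
            )

    def test_resample_refuses_extrapolation(self, library):
        target = WavenumberAxis(np.linspace(2700, 3000, 30))
        with pytest.raises(AxisMismatchError):
            library.resampled(target)
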