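"""Calibration: drift normalization, two-point fits, consumption constants."""

import numpy as np
import pytest

from mimsflux import (
    CalEntry,
    CalibrationModel,
    ConcentrationSeries,
    TraceMeta,
    TraceSet,
    equilibrium_concentration,
    estimate_consumption_constant,
    fit_two_point_calibration,
    normalize_to_reference,
    signal_to_concentration,
)
from mimsflux.errors import CalibrationError, NormalizationError


def _flat_trace(t, channels, **meta):
    return TraceSet(t, channels, meta=TraceMeta(**meta))


class TestNormalizeToReference:
    def test_constant_reference_is_identity(self):
        t = np.arange(0.0, 50.0)
        trace = _flat_trace(t, {32: 1e-9 + 1e-11 * t, 40: np.full_like(t, 2e-10)})
        out = normalize_to_reference(trace, 40)
        np.testing.assert_allclose(out.channel(32), trace.channel(32))

    def test_common_mode_drift_cancels_exactly(self):
        t = np.arange(0.0, 200.0)
        drift = 1 + 0.05 * np.sin(t / 20)
        clean = {32: 1e-9 * np.exp(-t / 500), 40: np.full_like(t, 2e-10)}
        drifted = _flat_trace(t, {mz: s * drift for mz, s in clean.items()})
        out = normalize_to_reference(drifted, 40)
        np.testing.assert_allclose(out.channel(32), clean[32], rtol=1e-12)
        np.testing.assert_allclose(out.channel(40), clean[40], rtol=1e-12)

    def test_idempotent(self):
        t = np.arange(0.0, 100.0)
        drift = 1 + 0.05 * np.sin(t / 10)
        trace = _flat_trace(t, {32: 1e-9 * drift, 40: 2e-10 * drift})
        once = normalize_to_reference(trace, 40)
        twice = normalize_to_reference(once, 40)
        np.testing.assert_allclose(twice.channel(32), once.channel(32))

    def test_nonpositive_reference_rejected(self):
        t = np.arange(0.0, 5.0)
        ref = np.array([1e-10, 1e-10, 0.0, 1e-10, 1e-10])
        trace = _flat_trace(t, {40: ref})
        with pytest.raises(NormalizationError, match="mz40"):
            normalize_to_reference(trace, 40)


class TestTwoPointCalibration:
    def _synthetic(self, registry, s=4e-10, b=2e-11, noise=0.0, seed=0):
        t = np.arange(0.0, 400.0)
        o2 = registry["O2"]
        c_air = equilibrium_concentration(o2, 25.0, o2.air_partial_pressure_atm)
        signal = np.full_like(t, b)
        signal[t >= 200] = b + s * c_air  # zero segment first, then air
        if noise:
            rng = np.random.default_rng(seed)
            signal = signal + rng.normal(0, noise * np.abs(signal))
        return _flat_trace(t, {32: signal}), c_air

    def test_exact_recovery_noise_free(self, registry):
        s, b = 4e-10, 2e-11
        trace, _ = self._synthetic(registry, s, b)
        cal = fit_two_point_calibration(
            trace, registry, (250, 390), (10, 190), ["O2"]
        )
        assert cal["O2"].sensitivity == pytest.approx(s, rel=1e-12)
        assert cal["O2"].baseline == pytest.approx(b, rel=1e-12)

    def test_species_absent_from_air_needs_spike(self, registry):
        t = np.arange(0.0, 400.0)
        trace = _flat_trace(t, {4: np.full_like(t, 1e-11)})
        with pytest.raises(CalibrationError, match="D2"):
            fit_two_point_calibration(trace, registry, (250, 390), (10, 190), ["D2"])

    def test_spiked_standard_calibrates_d2(self, registry):
        s, b, c_spike = 4e-10, 1e-11, 50.0
        t = np.arange(0.0, 400.0)
        sig = np.full_like(t, b)
        sig[t >= 200] = b + s * c_spike
        trace = _flat_trace(t, {4: sig})
        cal = fit_two_point_calibration(
            trace, registry, None, (10, 190), ["D2"],
            spiked={"D2": ((250, 390), c_spike)},
        )
        assert cal["D2"].sensitivity == pytest.approx(s, rel=1e-12)

    def test_unsteady_segment_rejected(self, registry):
        t = np.arange(0.0, 400.0)
        sig = 1e-10 * (1 + 0.2 * np.sin(t / 5))
        trace = _flat_trace(t, {32: sig})
        with pytest.raises(CalibrationError, match="not quasi-steady"):
            fit_two_point_calibration(trace, registry, (250, 390), (10, 190), ["O2"])

    def test_noisy_recovery_within_2_percent(self, registry):
        """Monte-Carlo: 1% channel noise, 200 points per segment, 100 seeds."""
        s = 4e-10
        errs = []
        for seed in range(100):
            trace, _ = self._synthetic(registry, s=s, noise=0.01, seed=seed)
            cal = fit_two_point_calibration(
                trace, registry, (200, 399), (0, 190), ["O2"],
                steadiness_rtol=0.05,
            )
            errs.append(abs(cal["O2"].sensitivity - s) / s)
        assert np.mean(errs) < 0.02
        assert np.quantile(errs, 0.95) < 0.02


class TestConsumptionConstant:
    def _series(self, c):
        t = np.arange(0.0, float(len(c)))
        return ConcentrationSeries(t, {"O2": np.asarray(c)})

    def test_exact_exponential(self):
        t = np.arange(0.0, 300.0)
        conc = ConcentrationSeries(t, {"O2": 200 * np.exp(-0.002 * t)})
        fit = estimate_consumption_constant(conc, "O2", (0, 299))
        assert fit.k == pytest.approx(0.002, rel=1e-10)
        assert not fit.clamped

    def test_constant_concentration_gives_zero(self):
        conc = self._series(np.full(100, 150.0))
        assert estimate_consumption_constant(conc, "O2", (0, 99)).k == 0.0

    def test_rising_signal_clamped_with_flag(self):
        t = np.arange(0.0, 100.0)
        conc = ConcentrationSeries(t, {"O2": 100 * np.exp(0.001 * t)})
        fit = estimate_consumption_constant(conc, "O2", (0, 99))
        assert fit.k == 0.0
        assert fit.clamped

    def test_scale_invariance(self):
        t = np.arange(0.0, 200.0)
        base = 100 * np.exp(-0.003 * t)
        k1 = estimate_consumption_constant(
            ConcentrationSeries(t, {"O2": base}), "O2", (0, 199)).k
        k2 = estimate_consumption_constant(
            ConcentrationSeries(t, {"O2": 7.3 * base}), "O2", (0, 199)).k
        assert k1 == pytest.approx(k2, rel=1e-12)

    def test_nonpositive_concentration_rejected(self):
        conc = self._series(np.array([1.0, 0.5, 0.0, 0.1, 0.2]))
        with pytest.raises(CalibrationError, match="non-positive"):
            estimate_consumption_constant(conc, "O2", (0, 4))

    def test_too_short_segment_rejected(self):
        conc = self._series(np.array([1.0, 0.9, 0.8, 0.7]))
        with pytest.raises(CalibrationError, match=">= 3"):
            estimate_consumption_constant(conc, "O2", (0, 1))

    def test_noisy_decay_within_5_percent(self):
        """Regression oracle: sigma = 1% of C0, 300 points, 100 seeds."""
        t = np.arange(0.0, 300.0)
        c0, k = 200.0, 0.002
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            c = c0 * np.exp(-k * t) + rng.normal(0, 0.01 * c0, t.size)
            conc = ConcentrationSeries(t, {"O2": np.maximum(c, 1e-6)})
            fit = estimate_consumption_constant(conc, "O2", (0, 299))
            errs.append(abs(fit.k - k) / k)
        assert np.mean(errs) < 0.05


class TestSignalToConcentration:
    def _cal(self, s=5e-10, b=1e-11, noise_sd=0.0):
        return CalibrationModel(
            {"O2": CalEntry(sensitivity=s, baseline=b, noise_sd=noise_sd)}
        )

    def test_baseline_maps_to_zero(self, registry):
        t = np.arange(0.0, 10.0)
        trace = _flat_trace(t, {32: np.full_like(t, 1e-11)})
        conc = signal_to_concentration(trace, self._cal(), registry)
        np.testing.assert_allclose(conc["O2"], 0.0)

    def test_linear_inverse(self, registry):
        s, b = 5e-10, 1e-11
        t = np.arange(0.0, 10.0)
        trace = _flat_trace(t, {32: np.full_like(t, b + s * 10.0)})
        conc = signal_to_concentration(trace, self._cal(s, b), registry)
        np.testing.assert_allclose(conc["O2"], 10.0, rtol=1e-12)

    def test_uncalibrated_species_rejected(self, registry):
        t = np.arange(0.0, 10.0)
        trace = _flat_trace(t, {44: np.full_like(t, 1e-11)})
        with pytest.raises(CalibrationError, match="CO2"):
            signal_to_concentration(trace, self._cal(), registry, ["CO2"])

    def test_small_negatives_clipped_and_counted(self, registry):
        s, b, noise_sd = 5e-10, 1e-10, 1e-12
        t = np.arange(0.0, 4.0)
        sig = np.array([b, b - 2 * noise_sd, b - 10 * noise_sd, b + s * 5])
        trace = _flat_trace(t, {32: sig})
        conc = signal_to_concentration(
            trace, self._cal(s, b, noise_sd), registry
        )
        assert conc.clipped_counts["O2"] == 1  # within 3 sigma: clipped
        assert conc.flagged_counts["O2"] == 1  # beyond 3 sigma: flagged
        assert conc["O2"][1] == 0.0
        assert conc["O2"][2] < 0  # left in place for inspection

    def test_simulator_round_trip(self, s1_run):
        """Calibration then conversion inverts the signal model exactly."""
        from mimsflux import load_gas_registry

        _, trace, truth, cal = s1_run
        reg = load_gas_registry()
        conc = signal_to_concentration(trace, cal, reg, ["O2", "18O2"])
        for g in ("O2", "18O2"):
            np.testing.assert_allclose(conc[g], truth.conc[g], rtol=1e-9, atol=1e-9)


def test_calibration_json_roundtrip(tmp_path):
    cal = CalibrationModel(
        {"O2": CalEntry(5e-10, 1e-11, 0.002, 1e-13, {"zero": (0.0, 10.0)})},
        reference_species="Ar",
        reference_anchor=2e-10,
    )
    path = cal.to_json(tmp_path / "cal.json")
    back = CalibrationModel.from_json(path)
    assert back["O2"] == cal["O2"]
    assert back.reference_species == "Ar"
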