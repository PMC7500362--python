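"""Ci affinity: DIC speciation, depletion curves, K_1/2 fit, HCO3- partition."""

import numpy as np
import pytest

from mimsflux import (
    ConcentrationSeries,
    FluxSeries,
    bicarbonate_uptake,
    compute_flux,
    depletion_curve,
    fit_k_half,
    preset,
    signal_to_concentration,
    simulate,
    smooth,
    speciate_dic,
)
from mimsflux.errors import AnalysisError
from mimsflux.simulator import truth_calibration


class TestSpeciateDic:
    def test_equal_split_at_pk1(self):
        co2, hco3 = speciate_dic(100.0, 6.35, pK1=6.35)
        assert co2 == pytest.approx(50.0)
        assert hco3 == pytest.approx(50.0)

    def test_acid_limit(self):
        co2, hco3 = speciate_dic(100.0, 4.0, pK1=6.35)
        assert co2 == pytest.approx(100.0, rel=1e-2)

    def test_henderson_hasselbalch_oracle(self):
        co2, hco3 = speciate_dic(100.0, 7.35, pK1=6.35)
        assert hco3 / co2 == pytest.approx(10.0, rel=1e-12)

    def test_dic_conserved_exactly(self):
        for pH in (4.5, 6.0, 7.2, 9.0):
            co2, hco3 = speciate_dic(123.456, pH)
            assert co2 + hco3 == pytest.approx(123.456, abs=1e-12)

    def test_out_of_range_ph_rejected(self):
        with pytest.raises(ValueError):
            speciate_dic(100.0, 11.0)


def _mm_depletion(vmax=10.0, k=5.0, n=200):
    """Synthetic depletion obeying v = Vmax*C/(K+C) pointwise."""
    t = np.arange(float(n))
    c = np.geomspace(60.0, 0.3, n)
    v = vmax * c / (k + c)
    conc = ConcentrationSeries(t, {"CO2": c})
    flux = FluxSeries(t, {"O2": v})
    return conc, flux, c, v


class TestDepletionCurve:
    def test_pairs_reproduce_rate_law(self):
        conc, flux, c, v = _mm_depletion()
        C, V = depletion_curve(conc, flux)
        np.testing.assert_array_equal(C, c)
        np.testing.assert_array_equal(V, v)

    def test_constant_co2_rejected(self):
        t = np.arange(50.0)
        conc = ConcentrationSeries(t, {"CO2": np.full(50, 20.0)})
        flux = FluxSeries(t, {"O2": np.full(50, 5.0)})
        with pytest.raises(AnalysisError, match="not depleting"):
            depletion_curve(conc, flux)

    def test_binning_drops_sparse_bins(self):
        conc, flux, c, v = _mm_depletion(n=100)
        C, V = depletion_curve(conc, flux, n_bins=10, min_bin_count=3)
        assert 5 <= C.size <= 10
        # binned curve still lies on the rate law within 5%
        np.testing.assert_allclose(V, 10.0 * C / (5.0 + C), rtol=0.05)


class TestFitKHalf:
    def test_exact_recovery(self):
        _, _, c, v = _mm_depletion(vmax=10.0, k=5.0)
        fit = fit_k_half(c, v)
        assert fit.K_half == pytest.approx(5.0, rel=1e-8)
        assert fit.V_max == pytest.approx(10.0, rel=1e-8)
        assert not fit.not_saturating

    def test_half_maximal_property(self):
        _, _, c, v = _mm_depletion(vmax=8.0, k=3.0)
        fit = fit_k_half(c, v)
        v_at_k = fit.V_max * fit.K_half / (fit.K_half + fit.K_half)
        assert v_at_k == pytest.approx(fit.V_max / 2)

    def test_order_invariance(self):
        _, _, c, v = _mm_depletion()
        rng = np.random.default_rng(0)
        perm = rng.permutation(c.size)
        f1 = fit_k_half(c, v)
        f2 = fit_k_half(c[perm], v[perm])
        assert f1.K_half == pytest.approx(f2.K_half, rel=1e-9)

    def test_non_saturating_flagged(self):
        c = np.linspace(0.1, 2.0, 20)  # max C far below K
        v = 10.0 * c / (50.0 + c)
        fit = fit_k_half(c, v)
        assert fit.not_saturating

    def test_too_few_levels_rejected(self):
        with pytest.raises(AnalysisError):
            fit_k_half(np.array([1.0, 1.0, 2.0, 2.0]), np.array([1, 1, 2, 2.0]))

    def test_bootstrap_ci_brackets_truth(self):
        _, _, c, v = _mm_depletion()
        rng = np.random.default_rng(5)
        noisy = v + rng.normal(0, 0.1, v.size)
        fit = fit_k_half(c, noisy, n_bootstrap=100, seed=1)
        lo, hi = fit.ci_K_half
        assert lo < 5.0 < hi


def _s4_k_half(registry, grown, seed=1, noise=0.0, window=0):
    spec = preset("s4_ci_depletion", seed=seed, grown=grown, noise_rel=noise)
    trace, truth = simulate(spec, registry)
    cal = truth_calibration(spec)
    conc = signal_to_concentration(trace, cal, registry, ["O2", "CO2"])
    fx = compute_flux(conc, cal, window=window)
    t_on = trace.event_time("light_on")
    pairs = depletion_curve(
        smooth(conc, window), fx,
        window=(t_on + 2 * max(window, 15), float(trace.time[-1])),
        monotone_rtol=0.05,
    )
    return fit_k_half(*pairs), spec


class TestScenarioS4:
    def test_k_half_recovered_noise_free(self, registry):
        fit, spec = _s4_k_half(registry, "air")
        assert fit.K_half == pytest.approx(spec.params["K_half"], rel=0.02)
        assert fit.V_max == pytest.approx(
            spec.params["pq"] * spec.params["V_max"], rel=0.02
        )

    def test_tenfold_contrast_preserved(self, registry):
        """Air-grown vs high-CO₂-grown: K ratio ≈ 10 within 15% (1% noise)."""
        ratios = []
        for seed in range(5):
            f_air, _ = _s4_k_half(registry, "air", seed=seed, noise=0.01, window=30)
            f_co2, _ = _s4_k_half(registry, "co2", seed=seed, noise=0.01, window=30)
            ratios.append(f_co2.K_half / f_air.K_half)
        assert np.mean(ratios) == pytest.approx(10.0, rel=0.15)

    def test_dic_conservation_audit(self, registry):
        """ΔDIC = −∫uptake − k·∫CO₂ (HCO₃⁻ does not cross the membrane)."""
        spec = preset("s4_ci_depletion", seed=1)
        spec.sample_dt = 0.1  # fine sampling so the audit integral resolves
        trace, truth = simulate(spec, registry)  # the light-on kink
        dic = truth.conc["CO2"] + truth.conc["HCO3"]
        uptake = truth.extra["total_ci_uptake"]
        leak = spec.instrument.k("CO2") * truth.conc["CO2"]
        lhs = dic[-1] - dic[0]
        rhs = -np.trapezoid(uptake + leak, trace.time)
        # tolerance set by the single RK4 step straddling the light-on event
        assert lhs == pytest.approx(rhs, rel=1e-3)


class TestBicarbonateUptake:
    def _series(self, n, net_o2, net_co2):
        t = np.arange(float(n))
        return (
            FluxSeries(t, {"O2": np.full(n, net_o2)}),
            FluxSeries(t, {"CO2": np.full(n, net_co2)}),
        )

    def test_arithmetic_partition(self):
        # chem supply zero, CO2 uptake 4, net O2 10, PQ 1 -> HCO3 uptake 6
        o2, co2 = self._series(5, 10.0, -4.0)
        res = bicarbonate_uptake(
            o2, co2, np.zeros(5), np.zeros(5), pH=7.2, k_h=0.0, pq=1.0
        )
        np.testing.assert_allclose(res.co2_uptake, 4.0)
        np.testing.assert_allclose(res.hco3_uptake, 6.0)

    def test_partition_sums_to_total(self):
        rng = np.random.default_rng(2)
        n = 50
        o2 = FluxSeries(np.arange(float(n)), {"O2": rng.normal(5, 1, n)})
        co2 = FluxSeries(np.arange(float(n)), {"CO2": rng.normal(-2, 1, n)})
        res = bicarbonate_uptake(
            o2, co2, rng.uniform(1, 20, n), rng.uniform(50, 100, n),
            pH=7.2, pq=1.2,
        )
        np.testing.assert_allclose(
            res.co2_uptake + res.hco3_uptake, res.total_ci_uptake, rtol=1e-12
        )

    def test_all_co2_means_zero_hco3(self):
        o2, co2 = self._series(5, 10.0, -10.0)
        res = bicarbonate_uptake(
            o2, co2, np.zeros(5), np.zeros(5), pH=7.2, k_h=0.0, pq=1.0
        )
        np.testing.assert_allclose(res.hco3_uptake, 0.0, atol=1e-12)

    def test_extracellular_ca_refused(self):
        o2, co2 = self._series(5, 10.0, -4.0)
        with pytest.raises(AnalysisError, match="extracellular"):
            bicarbonate_uptake(
                o2, co2, np.zeros(5), np.zeros(5), pH=7.2,
                extracellular_ca=True,
            )

    def test_preferential_hco3_transport_recovered(self, registry):
        """Simulated 70% HCO₃⁻ share recovered within 10%."""
        spec = preset("s4_ci_depletion", seed=4, params={"hco3_share": 0.7})
        trace, truth = simulate(spec, registry)
        cal = truth_calibration(spec)
        conc = signal_to_concentration(trace, cal, registry, ["O2", "CO2"])
        fx = compute_flux(conc, cal, window=0)
        hco3 = truth.conc["HCO3"]
        res = bicarbonate_uptake(
            fx, fx, conc["CO2"], hco3,
            pH=spec.meta.pH, pK1=spec.params["pK1"], k_h=spec.params["k_h"],
            pq=spec.params["pq"],
        )
        sel = (trace.time > 100) & (trace.time < 500)
        share = np.mean(res.hco3_uptake[sel]) / np.mean(res.total_ci_uptake[sel])
        assert share == pytest.approx(0.7, rel=0.10)
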