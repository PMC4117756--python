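import numpy as np
import pytest

import helifret as hf


class TestEstimateRate:
    def test_reciprocal_mean(self):
        est = hf.estimate_rate([2.0, 2.0, 2.0], substep="A")
        assert est.rate == pytest.approx(0.5)
        assert est.sem == pytest.approx(0.5 / np.sqrt(3))
        assert est.n == 3

    def test_empty_or_fully_censored_input_raises(self):
        with pytest.raises(ValueError, match="S"):
            hf.estimate_rate([], substep="S")
        with pytest.raises(ValueError, match="A"):
            hf.estimate_rate([1.0, 2.0], censored=[True, True], substep="A")
        with pytest.raises(ValueError):
            hf.estimate_rate([1.0, -0.5])

    def test_sampling_consistency_and_small_bias(self):
        """On Exp(0.1) samples the estimator lands within 3 SEM and its
        bias at n=1000 is below 1%."""
        rng = np.random.default_rng(7)
        dwells = rng.exponential(10.0, 1000)
        est = hf.estimate_rate(dwells)
        assert abs(est.rate - 0.1) < 3 * est.sem
        # bias of the exponential-MLE rate is k/(n-1); verify empirically
        reps = [hf.estimate_rate(rng.exponential(10.0, 1000)).rate for _ in range(300)]
        assert abs(np.mean(reps) - 0.1) / 0.1 < 0.01

    def test_bootstrap_sem_agrees_with_delta_method(self):
        rng = np.random.default_rng(11)
        dwells = rng.exponential(5.0, 400)
        d = hf.estimate_rate(dwells)
        b = hf.estimate_rate(dwells, n_boot=1000, seed=1)
        assert b.sem == pytest.approx(d.sem, rel=0.25)

    def test_censored_dwells_excluded_and_counted(self):
        est = hf.estimate_rate([1.0, 1.0, 50.0], censored=[False, False, True])
        assert est.rate == pytest.approx(1.0)
        assert est.n == 2 and est.n_censored == 1


def test_off_rate_from_total_bound_times():
    est = hf.estimate_off_rate([10.0, 10.0])
    assert est.rate == pytest.approx(0.1)
    assert est.substep == "off"


def test_mutant_off_rate_exceeds_wild_type(wt_dwell_table):
    """The dsRBD-truncation mutant leaves the RNA much faster than wild
    type under the presets."""
    p = hf.preset_params("delta_dsRBD")
    cond = hf.Condition("delta_dsRBD", 320e-9, 1e-3)
    ds = hf.simulate_dataset(p, [cond], 80, 250.0, 23)
    dd_table = hf.analyze_traces(ds.traces[cond.key()], condition_key=cond.key())
    wt_off = hf.estimate_off_rate(wt_dwell_table.bound_times())
    dd_off = hf.estimate_off_rate(dd_table.bound_times())
    z = (dd_off.rate - wt_off.rate) / np.hypot(dd_off.sem, wt_off.sem)
    assert z > 3.0


class TestAssociationFit:
    def test_exact_line_recovers_association_constant(self):
        conc = np.array([10e-9, 20e-9, 40e-9, 80e-9])
        fit = hf.fit_association_constant(conc, 2.61e6 * conc)
        assert fit.slope == pytest.approx(2.61e6, rel=1e-12)
        assert fit.intercept == 0.0

    def test_zero_rates_give_zero_slope(self):
        fit = hf.fit_association_constant([1e-9, 2e-9, 4e-9], [0.0, 0.0, 0.0])
        assert fit.slope == 0.0

    def test_single_concentration_rejected(self):
        with pytest.raises(ValueError):
            hf.fit_association_constant([1e-9, 1e-9], [0.1, 0.2])

    def test_end_to_end_recovery_from_simulated_waits(self, wt_params):
        """Binding-dwell simulations across 10-80 nM recover k_on within
        3 SE of the generating constant."""
        rng = np.random.default_rng(2024)
        conc = np.array([10e-9, 20e-9, 40e-9, 80e-9])
        rates, sems = [], []
        for c in conc:
            est = hf.estimate_rate(rng.exponential(1.0 / (wt_params.k_on * c), 200))
            rates.append(est.rate)
            sems.append(est.sem)
        fit = hf.fit_association_constant(conc, rates, sems)
        assert abs(fit.slope - wt_params.k_on) < 3 * fit.slope_se


class TestMichaelisMenten:
    GRID = np.array([10, 25, 50, 100, 250, 500, 1000]) * 1e-6

    def test_exact_curve_recovered(self):
        v = 1.0 * self.GRID / (26e-6 + self.GRID)
        fit = hf.fit_michaelis_menten(self.GRID, v)
        assert fit.converged
        assert fit.vmax == pytest.approx(1.0, rel=1e-6)
        assert fit.km == pytest.approx(26e-6, rel=1e-6)

    def test_saturating_grid_leaves_km_unconstrained(self):
        x = np.array([0.3, 0.5, 1.0, 2.0])  # all >> Km
        v = 1.0 * x / (26e-6 + x)
        fit = hf.fit_michaelis_menten(x, v + np.array([1e-4, -1e-4, 5e-5, -5e-5]))
        assert fit.vmax == pytest.approx(1.0, rel=0.01)
        assert fit.km_se > abs(fit.km)  # flagged by a huge relative SE

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            hf.fit_michaelis_menten([1e-5, 1e-4], [0.3, 0.8])

    def test_end_to_end_recovery_from_simulated_dwells(self, wt_params):
        rng = np.random.default_rng(5)
        rates, sems = [], []
        for atp in self.GRID:
            gen = wt_params.k_unw * atp / (wt_params.Km_atp + atp)
            est = hf.estimate_rate(rng.exponential(1.0 / gen, 200))
            rates.append(est.rate)
            sems.append(est.sem)
        fit = hf.fit_michaelis_menten(self.GRID, rates, sems)
        assert fit.converged
        assert abs(fit.km - wt_params.Km_atp) < 3 * fit.km_se


class TestFoldChange:
    def test_identical_inputs_give_unit_ratios(self):
        ests = [hf.RateEstimate(s, 0.5, 0.05, 10) for s in "BAUSR"]
        fc = hf.fold_change(ests, ests)
        assert np.allclose(fc["ratio"], 1.0)

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError, match="labels differ"):
            hf.fold_change([hf.RateEstimate("A", 1, 0.1, 5)],
                           [hf.RateEstimate("U", 1, 0.1, 5)])

    def test_temperature_ratio_recovery(self, wt_params):
        """Ground-truth dwells at RT vs 37C give per-substep ratios whose
        95% CIs contain the generating temp factor, all inside 2-5x."""
        from helifret.params import effective_rates

        def truth_rates(cond, seed):
            rates = effective_rates(wt_params, cond)
            comp = rates["off"] + rates["bleach"]
            gen = {"B": rates["b"], "A": rates["a"] + comp, "U": rates["u"] + comp,
                   "S": rates["s"] + comp, "R": rates["r"] + comp}
            pools = {k: [] for k in gen}
            for i in range(120):
                _, path = hf.simulate_trace(wt_params, cond, 150.0,
                                            np.random.SeedSequence([seed, i]))
                segs = path.segments
                for j, s in enumerate(segs[:-1]):
                    nxt = segs[j + 1].label
                    if s.label == "B" and nxt == "A":
                        pools["B"].append(s.dwell)
                    elif s.label == "A" and nxt == "U":
                        pools["A"].append(s.dwell)
                    elif s.label == "U" and nxt == "S":
                        pools["U"].append(s.dwell)
                    elif s.label == "S" and nxt in ("R", "separated"):
                        pools["S"].append(s.dwell)
                    elif s.label == "R" and nxt == "U":
                        pools["R"].append(s.dwell)
            return [hf.estimate_rate(v, substep=k) for k, v in pools.items()]

        rt = truth_rates(hf.Condition(), 60)
        hot = truth_rates(hf.Condition(temperature_label="37C"), 61)
        fc = hf.fold_change(rt, hot).set_index("substep")
        for sub in "BAUSR":
            row = fc.loc[sub]
            assert row["ci_low"] <= wt_params.temp_factor <= row["ci_high"], sub
            assert 2.0 <= row["ratio"] <= 5.0, sub


class TestIsotherm:
    def test_exact_hyperbola_recovers_kd(self):
        c = np.array([0, 5, 10, 25, 50, 100, 250, 1000]) * 1e-9
        pol = 0.1 + 0.2 * c / (50e-9 + c)
        fit = hf.fit_binding_isotherm(c, pol)
        assert fit.identifiable
        assert fit.kd == pytest.approx(50e-9, rel=1e-6)
        assert fit.p_ceiling > fit.p_floor

    def test_constant_polarization_flagged_unidentifiable(self):
        c = np.array([0, 10e-9, 100e-9, 1e-6])
        fit = hf.fit_binding_isotherm(c, np.full(4, 0.15))
        assert not fit.identifiable

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            hf.fit_binding_isotherm([0, 1e-9, 1e-8], [0.1, 0.2, 0.3])

    def test_noisy_recovery_within_ten_percent(self):
        """Median fitted Kd over noisy replicates within 10% of truth."""
        rng = np.random.default_rng(31)
        c = np.array([0, 5, 10, 25, 50, 100, 250, 1000]) * 1e-9
        kds = []
        for _ in range(150):
            pol = 0.1 + 0.2 * c / (50e-9 + c)
            noisy = pol * (1 + rng.normal(0, 0.05, c.size))
            fit = hf.fit_binding_isotherm(c, noisy)
            if fit.converged:
                kds.append(fit.kd)
        assert abs(np.median(kds) - 50e-9) / 50e-9 < 0.10


def test_rate_vs_covariate_slope_flat_series():
    rng = np.random.default_rng(3)
    x = np.array([1.0, 2.0, 4.0, 8.0])
    y = 0.5 + rng.normal(0, 0.01, 4)
    fit = hf.rate_vs_covariate_slope(x, y, np.full(4, 0.01))
    assert abs(fit.slope) < 3 * fit.slope_se
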