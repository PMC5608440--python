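"""Transition detection, order/rate maps, nulls, and scaled-time averaging."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from mbcascade.analysis import (
    detect_transitions, order_map, pair_rates, pair_rate_samples,
    bootstrap_ci, independent_null_pdf, ks_critical_value,
    ks_independence_test, order_pvalue, scaled_time_average, compare_setups,
    estimate_rate, load_event_table, save_event_table,
)
from mbcascade.dynamics import ChiTrajectory, DynamicsParams

from conftest import random_event_table


def make_traj(chi_rows, module_names=None, save=500, direction="power", seed=0):
    chi = np.asarray(chi_rows, dtype=float)
    if chi.ndim == 1:
        chi = chi[:, None]
    module_names = module_names or [f"M{i+1}" for i in range(chi.shape[1])]
    steps = np.arange(chi.shape[0]) * save
    params = DynamicsParams(n_steps=int(steps[-1]) or 1, save_interval=save)
    return ChiTrajectory(steps, chi, module_names, direction, seed, params)


class TestDetectTransitions:
    def test_simple_crossing(self):
        traj = make_traj([-2, -2, 2, 2])
        ev = detect_transitions(traj, chi_threshold=1.0, persistence=1)
        assert ev.loc[0, "tau"] == 2 * 500
        assert not ev.loc[0, "censored"]

    def test_never_crossing_is_censored(self):
        traj = make_traj([-2, -2, 0.5, -2])
        ev = detect_transitions(traj, 1.0, 1)
        assert ev.loc[0, "censored"]
        assert np.isnan(ev.loc[0, "tau"])

    def test_subthreshold_excursion_ignored(self):
        traj = make_traj([-2, 0.5, -2, 2])
        ev = detect_transitions(traj, 1.0, 1)
        assert ev.loc[0, "tau"] == 3 * 500

    def test_persistence_requires_consecutive_frames(self):
        traj = make_traj([-2, 2, -2, 2, 2, -2])
        ev = detect_transitions(traj, 1.0, 2)
        # the single-frame spikes at frames 1 and 3 do not count; frames 3-4
        # are the first two consecutive frames above threshold
        assert ev.loc[0, "tau"] == 3 * 500

    def test_recovery_targets_pre_state(self):
        traj = make_traj([2, 2, -2, -2], direction="recovery")
        ev = detect_transitions(traj, 1.0, 1)
        assert ev.loc[0, "tau"] == 2 * 500

    def test_empty_trajectory_raises(self):
        traj = make_traj([-2, 2])
        traj.steps = np.array([])
        traj.chi = np.zeros((0, 1))
        with pytest.raises(ValueError, match="empty"):
            detect_transitions(traj, 1.0, 1)


def table_from_taus(tau_rows, t_end=100.0):
    """tau_rows: list per trajectory of {module: tau or None}."""
    rows = []
    for t, d in enumerate(tau_rows):
        for m, tau in d.items():
            rows.append({"trajectory": t, "module": m,
                         "tau": np.nan if tau is None else tau,
                         "censored": tau is None, "t_end": t_end,
                         "frame_steps": 1})
    return pd.DataFrame(rows)


class TestOrderMap:
    def test_simple_fractions(self):
        rows = [{"a": 1.0, "b": 2.0}] * 27 + [{"a": 2.0, "b": 1.0}] * 3
        om = order_map(table_from_taus(rows))
        ia, ib = om.modules.index("a"), om.modules.index("b")
        assert om.p_order[ia, ib] == pytest.approx(0.9)
        assert om.p_order[ib, ia] == pytest.approx(0.1)

    def test_censoring_makes_sums_less_than_one(self):
        rows = [{"a": 1.0, "b": 2.0}] * 24 + [{"a": 1.0, "b": None}] * 6
        om = order_map(table_from_taus(rows))
        ia, ib = om.modules.index("a"), om.modules.index("b")
        assert om.p_order[ia, ib] == pytest.approx(0.8)
        assert om.p_order[ib, ia] == pytest.approx(0.0)

    def test_pair_probability_partition(self):
        """P(a first) + P(b first) + P(undecided) = 1 for every pair."""
        rng = np.random.default_rng(0)
        ev = random_event_table(rng, K=4, n_traj=25)
        om = order_map(ev)
        piv = ev.pivot(index="trajectory", columns="module", values="tau")
        for a in range(4):
            for b in range(a + 1, 4):
                ta, tb = piv[om.modules[a]], piv[om.modules[b]]
                undecided = (ta.isna() | tb.isna() | (ta == tb)).mean()
                assert om.p_order[a, b] + om.p_order[b, a] + undecided \
                    == pytest.approx(1.0)

    def test_matches_bruteforce_counting(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            ev = random_event_table(rng, K=3, n_traj=15)
            om = order_map(ev)
            piv = ev.pivot(index="trajectory", columns="module", values="tau")
            for a in range(3):
                for b in range(3):
                    if a == b:
                        continue
                    ta, tb = piv[om.modules[a]], piv[om.modules[b]]
                    count = ((ta < tb) & ta.notna() & tb.notna()).sum()
                    assert om.p_order[a, b] == pytest.approx(count / 15)

    def test_sorted_by_descending_score(self):
        rows = [{"a": 3.0, "b": 1.0, "c": 2.0}] * 10
        om = order_map(table_from_taus(rows))
        assert om.sorted_modules == ["b", "c", "a"]


class TestPairRates:
    def test_reciprocal_average(self):
        # dt of 10 and 5 (in 1e4-step units) -> (0.1 + 0.2)/2
        rows = [{"a": 1e4, "b": 11e4}, {"a": 1e4, "b": 6e4}]
        ev = table_from_taus(rows, t_end=200e4)
        vals = pair_rate_samples(ev, "a", "b")
        np.testing.assert_allclose(sorted(vals), [0.1, 0.2])
        rm = pair_rates(ev, mask_threshold=2)
        ia, ib = rm.modules.index("a"), rm.modules.index("b")
        assert rm.k[ia, ib] == pytest.approx(0.15)

    def test_censored_partner_uses_end_time(self):
        rows = [{"a": 80e4, "b": None}]
        ev = table_from_taus(rows, t_end=100e4)
        vals = pair_rate_samples(ev, "a", "b")
        np.testing.assert_allclose(vals, [0.05])

    def test_mask_below_threshold(self):
        rows = [{"a": 1.0, "b": 2.0}] * 5
        rm = pair_rates(table_from_taus(rows), mask_threshold=7)
        ia, ib = rm.modules.index("a"), rm.modules.index("b")
        assert np.isnan(rm.k[ia, ib])
        assert rm.n[ia, ib] == 5

    def test_frame_floor_prevents_divergence(self):
        ev = table_from_taus([{"a": 5000.0, "b": 5000.0 + 1}])
        ev["frame_steps"] = 500
        vals = pair_rate_samples(ev, "a", "b")
        np.testing.assert_allclose(vals, [1e4 / 500])

    def test_floored_mean_matches_numeric_integration(self):
        """E[1/max(dt, floor)] for exponential dt, against quadrature."""
        rng = np.random.default_rng(2)
        rate, floor = 0.1, 0.5
        dts = np.maximum(rng.exponential(1 / rate, size=200_000), floor)
        mc = np.mean(1.0 / dts)
        exact = (1.0 / floor) * (1 - np.exp(-rate * floor)) + integrate.quad(
            lambda t: rate * np.exp(-rate * t) / t, floor, np.inf)[0]
        assert mc == pytest.approx(exact, rel=0.01)


class TestBootstrap:
    def test_degenerate_sample(self):
        lo, hi = bootstrap_ci(np.full(10, 3.3), seed=0)
        assert lo == pytest.approx(3.3)
        assert hi == pytest.approx(3.3)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(3)
        x = rng.exponential(size=30)
        assert bootstrap_ci(x, seed=5) == bootstrap_ci(x, seed=5)
        assert bootstrap_ci(x, seed=5) != bootstrap_ci(x, seed=6)

    def test_interval_brackets_sample_mean(self):
        rng = np.random.default_rng(4)
        x = rng.exponential(size=50)
        lo, hi = bootstrap_ci(x, seed=0)
        assert lo < x.mean() < hi


class TestIndependentNull:
    def test_symmetric_rates(self):
        pdf, cdf = independent_null_pdf(1.0, 1.0)
        assert pdf(0.0) == pytest.approx(0.5)
        assert 1.0 - cdf(0.0) == pytest.approx(0.5)

    def test_normalization(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            ka, kb = rng.uniform(0.05, 5.0, size=2)
            pdf, _ = independent_null_pdf(ka, kb)
            total, _ = integrate.quad(pdf, -np.inf, np.inf)
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_asymmetric_tail_probability(self):
        # P(dt > 0) = P(tau_b > tau_a) = k_a / (k_a + k_b)
        _, cdf = independent_null_pdf(2.0, 1.0)
        assert 1.0 - cdf(0.0) == pytest.approx(2.0 / 3.0)

    def test_cdf_matches_monte_carlo(self):
        rng = np.random.default_rng(6)
        ka, kb = 2.0, 1.0
        n = 200_000
        dt = rng.exponential(1 / kb, n) - rng.exponential(1 / ka, n)
        _, cdf = independent_null_pdf(ka, kb)
        xs = np.linspace(-4, 6, 101)
        ecdf = np.searchsorted(np.sort(dt), xs) / n
        assert np.abs(ecdf - cdf(xs)).max() < 0.01

    def test_nonpositive_rates_raise(self):
        with pytest.raises(ValueError):
            independent_null_pdf(0.0, 1.0)


class TestKSTest:
    def test_critical_value_n30(self):
        assert ks_critical_value(30, 0.05) == pytest.approx(0.2417, abs=5e-5)

    def test_point_mass_in_tail_rejects(self):
        res = ks_independence_test(np.full(30, 100.0), 1.0, 1.0)
        assert res.statistic > 0.99
        assert res.reject

    def test_null_samples_usually_accepted(self):
        rng = np.random.default_rng(7)
        dt = rng.exponential(1.0, 30) - rng.exponential(1.0, 30)
        res = ks_independence_test(dt, 1.0, 1.0)
        assert res.critical_value == pytest.approx(0.2417, abs=5e-5)
        assert res.statistic < res.critical_value

    def test_small_sample_raises(self):
        with pytest.raises(ValueError):
            ks_independence_test(np.array([1.0, 2.0]), 1.0, 1.0)

    def test_estimate_rate_from_events(self):
        ev = table_from_taus([{"a": 2e4}, {"a": 4e4}, {"a": None}])
        assert estimate_rate(ev, "a") == pytest.approx(1e4 / 3e4)


class TestOrderPvalue:
    def test_unanimous(self):
        res = order_pvalue(30, 0, K=8, method=None)
        assert res["raw"] == pytest.approx(2 * 2.0**-30, rel=1e-9)

    def test_eight_two(self):
        res = order_pvalue(8, 2, K=8, method=None)
        assert res["raw"] == pytest.approx(112 / 1024)

    def test_balanced_capped_at_one(self):
        res = order_pvalue(5, 5, K=8)
        assert res["raw"] == pytest.approx(1.0)
        assert res["corrected"] == pytest.approx(1.0)

    def test_bonferroni_multiplies_by_pair_count(self):
        res = order_pvalue(9, 1, K=4)
        assert res["corrected"] == pytest.approx(min(1.0, res["raw"] * 6))


class TestScaledTime:
    def _ramp_traj(self, tau_a, tau_b, tau_t, seed, n=50, save=500):
        """chi ramps crossing the detection threshold at the given times."""
        steps = np.arange(n) * save

        def ramp(tau):
            return np.where(steps < tau, -2.0, 2.0)

        chi = np.stack([ramp(tau_a), ramp(tau_b), ramp(tau_t)], axis=1)
        params = DynamicsParams(n_steps=int(steps[-1]), save_interval=save)
        return ChiTrajectory(steps, chi, ["A", "B", "T"], "power", seed, params)

    def test_target_at_first_anchor_crosses_at_zero(self):
        trajs = [self._ramp_traj(5000, 15000, 5000, s) for s in range(3)]
        out = scaled_time_average(trajs, "A", "B", "T", persistence=1)
        sign_change = out["s"][np.argmax(out["chi_mean"].to_numpy() > 0)]
        assert sign_change == pytest.approx(0.0, abs=0.05)

    def test_target_midway_crosses_at_half(self):
        trajs = [self._ramp_traj(5000, 15000, 10000, s) for s in range(3)]
        out = scaled_time_average(trajs, "A", "B", "T", persistence=1)
        sign_change = out["s"][np.argmax(out["chi_mean"].to_numpy() > 0)]
        assert sign_change == pytest.approx(0.5, abs=0.05)
        assert (out["n_included"] == 3).all()

    def test_censored_anchor_excluded(self):
        good = self._ramp_traj(5000, 15000, 10000, 0)
        bad = self._ramp_traj(5000, 10**9, 10000, 1)  # B never transits
        out = scaled_time_average([good, bad], "A", "B", "T", persistence=1)
        assert (out["n_included"] == 1).all()

    def test_average_of_known_ramps(self):
        """The ensemble mean equals the analytic average of the step ramps."""
        taus = [(5000, 15000, 7500), (5000, 15000, 12500)]
        trajs = [self._ramp_traj(a, b, t, i) for i, (a, b, t) in enumerate(taus)]
        out = scaled_time_average(trajs, "A", "B", "T", persistence=1)
        # targets cross at s = 0.25 and 0.75: mean is 0 between, +-2 outside
        mid = out[(out["s"] > 0.3) & (out["s"] < 0.7)]["chi_mean"]
        np.testing.assert_allclose(mid, 0.0, atol=1e-9)
        assert out[out["s"] < 0.2]["chi_mean"].iloc[0] == pytest.approx(-2.0)
        assert out[out["s"] > 0.8]["chi_mean"].iloc[-1] == pytest.approx(2.0)


class TestCompareSetups:
    def _report(self, rows):
        ev = table_from_taus(rows)
        return {"order": order_map(ev), "rates": pair_rates(ev, mask_threshold=1)}

    def test_identical_reports_zero_deltas(self):
        rows = [{"a": 1.0, "b": 2.0}] * 10
        table = compare_setups(self._report(rows), {"same": self._report(rows)})
        np.testing.assert_allclose(table["delta_p_order"], 0.0)
        # masked (never-observed) pairs stay masked; observed pairs match
        observed = table["delta_k"].notna()
        assert observed.any()
        np.testing.assert_allclose(table.loc[observed, "delta_k"], 0.0)

    def test_flipped_pair_flagged(self):
        ref = self._report([{"a": 1.0, "b": 2.0}] * 10)
        flip = self._report([{"a": 2.0, "b": 1.0}] * 10)
        table = compare_setups(ref, {"flip": flip})
        row = table[(table["first"] == "a") & (table["second"] == "b")].iloc[0]
        assert row["delta_p_order"] == pytest.approx(-1.0)

    def test_module_mismatch_raises(self):
        ref = self._report([{"a": 1.0, "b": 2.0}] * 10)
        other = self._report([{"a": 1.0, "c": 2.0}] * 10)
        with pytest.raises(ValueError, match="module set"):
            compare_setups(ref, {"bad": other})


class TestEventTableIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        ev = random_event_table(rng, K=3, n_traj=5)
        path = tmp_path / "events.csv"
        save_event_table(ev, path)
        back = load_event_table(path)
        pd.testing.assert_frame_equal(
            back.reset_index(drop=True), ev.reset_index(drop=True),
            check_dtype=False)

    def test_missing_columns_raise(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"trajectory": [0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            load_event_table(path)


class TestPlots:
    def test_heatmaps_render(self, tmp_path):
        import matplotlib
        matplotlib.use("Agg")
        from mbcascade.analysis import plot_order_map, plot_rate_map

        rows = [{"a": 1.0, "b": 2.0}] * 10
        ev = table_from_taus(rows)
        ax = plot_order_map(order_map(ev), sort=True)
        ax.figure.savefig(tmp_path / "order.png")
        ax2 = plot_rate_map(pair_rates(ev, mask_threshold=1))
        ax2.figure.savefig(tmp_path / "rates.png")
        assert (tmp_path / "order.png").stat().st_size > 0
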