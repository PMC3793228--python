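"""Yule/birth-death simulators: stopping rules, distributional checks,
parameter recovery, and synthetic rate tables."""

import numpy as np
import pytest
from scipy import stats

import paramodiv as pv
from paramodiv.errors import ValidationError


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(birth_rate=0.0, stop_time=1.0),
            dict(birth_rate=1.0, death_rate=1.0, stop_time=1.0),
            dict(birth_rate=1.0),
            dict(birth_rate=1.0, stop_time=1.0, stop_tips=5),
            dict(birth_rate=1.0, stop_time=-1.0),
            dict(birth_rate=1.0, stop_tips=1),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            pv.SimulationConfig(**kwargs)

    def test_yule_refuses_nonzero_death(self):
        with pytest.raises(ValidationError, match="death_rate"):
            pv.simulate_yule(
                pv.SimulationConfig(birth_rate=1.0, death_rate=0.5, stop_time=1.0)
            )


class TestYule:
    def test_stop_time_fixes_crown_age(self):
        for seed in range(5):
            t = pv.simulate_yule(
                pv.SimulationConfig(birth_rate=0.5, stop_time=5.0, seed=seed)
            )
            assert pv.crown_age(t) == pytest.approx(5.0, abs=1e-9)

    def test_stop_tips_fixes_tip_count(self):
        t = pv.simulate_yule(pv.SimulationConfig(birth_rate=1.0, stop_tips=64, seed=0))
        assert t.n_tips == 64
        ok, _ = pv.check_ultrametric(t, tol=1e-9)
        assert ok

    def test_all_trees_ultrametric_at_tight_tolerance(self):
        for seed in range(10):
            t = pv.simulate_yule(
                pv.SimulationConfig(birth_rate=0.8, stop_time=4.0, seed=seed)
            )
            ok, dev = pv.check_ultrametric(t, tol=1e-9)
            assert ok, dev

    def test_mean_tip_count_matches_crown_yule_expectation(self):
        # crown start: E[N(t)] = 2 exp(lambda t)
        lam, t_stop, reps = 0.4, 4.0, 2000
        counts = np.array(
            [
                pv.simulate_yule(
                    pv.SimulationConfig(birth_rate=lam, stop_time=t_stop, seed=s)
                ).n_tips
                for s in range(reps)
            ]
        )
        expected = 2 * np.exp(lam * t_stop)
        # each crown lineage's count is geometric with mean e^{lam t}
        m = np.exp(lam * t_stop)
        var = 2 * m * (m - 1)
        sigma = np.sqrt(var / reps)
        assert abs(counts.mean() - expected) < 3 * sigma

    def test_tip_count_distribution_geometric_sum(self):
        # single crown lineage count ~ Geometric(e^{-lam t}); crown total is
        # the sum of two iid geometrics -> chi-square on binned counts
        lam, t_stop, reps = 0.5, 3.0, 2000
        counts = np.array(
            [
                pv.simulate_yule(
                    pv.SimulationConfig(birth_rate=lam, stop_time=t_stop, seed=10_000 + s)
                ).n_tips
                for s in range(reps)
            ]
        )
        p = np.exp(-lam * t_stop)
        # P(total = k) = (k-1) p^2 (1-p)^(k-2), k >= 2 (negative binomial r=2)
        ks = np.arange(2, 60)
        pmf = (ks - 1) * p**2 * (1 - p) ** (ks - 2)
        bins = [2, 4, 6, 9, 13, 18, 25, 60]
        expected = []
        observed = []
        for lo, hi in zip(bins[:-1], bins[1:]):
            mask = (ks >= lo) & (ks < hi)
            expected.append(pmf[mask].sum() * reps)
            observed.append(((counts >= lo) & (counts < hi)).sum())
        tail_exp = reps - sum(expected)
        expected.append(max(tail_exp, 1e-9))
        observed.append(reps - sum(observed))
        chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
        crit = stats.chi2.ppf(0.999, df=len(expected) - 1)
        assert chi2 < crit

    def test_same_seed_byte_identical_serialization(self):
        cfg = pv.SimulationConfig(birth_rate=0.7, stop_tips=30, seed=99)
        a = pv.simulate_yule(cfg).as_newick(precision=9)
        b = pv.simulate_yule(cfg).as_newick(precision=9)
        assert a == b

    def test_estimator_consistency_on_yule_trees(self):
        # the median crown estimate over many trees recovers lambda at
        # lambda*t >= 3 (single-tree estimates scatter with sd ~ 1/(lambda t))
        lam, t_stop = 1.0, 3.5
        estimates = [
            pv.pure_birth_rate(
                pv.simulate_yule(
                    pv.SimulationConfig(birth_rate=lam, stop_time=t_stop, seed=seed)
                ).n_tips,
                t_stop,
                n0=2,
            )
            for seed in range(500)
        ]
        assert abs(np.median(estimates) - lam) / lam < 0.10


class TestBirthDeath:
    def test_mu_zero_distribution_matches_yule(self):
        # KS test on tip counts at mu=0 vs simulate_yule
        lam, t_stop, reps = 0.5, 3.0, 2000
        yule = [
            pv.simulate_yule(
                pv.SimulationConfig(birth_rate=lam, stop_time=t_stop, seed=s)
            ).n_tips
            for s in range(reps)
        ]
        bd = [
            pv.simulate_birth_death(
                pv.SimulationConfig(
                    birth_rate=lam, death_rate=0.0, stop_time=t_stop,
                    condition_on_survival=True, seed=50_000 + s,
                )
            ).n_tips
            for s in range(reps)
        ]
        assert stats.ks_2samp(yule, bd).pvalue > 0.01

    def test_conditioning_guarantees_two_tips(self):
        for seed in range(20):
            t = pv.simulate_birth_death(
                pv.SimulationConfig(
                    birth_rate=1.0, death_rate=0.5, stop_time=3.0,
                    condition_on_survival=True, seed=seed,
                )
            )
            assert t.n_tips >= 2
            ok, _ = pv.check_ultrametric(t, tol=1e-9)
            assert ok

    def test_extinction_corrected_estimator_recovers_net_rate(self):
        # eps-matched crown estimator averaged over conditioned trees
        lam, mu, t_stop = 1.0, 0.5, 3.0
        eps, r_true = mu / lam, lam - mu
        estimates = []
        for seed in range(2000):
            tree = pv.simulate_birth_death(
                pv.SimulationConfig(
                    birth_rate=lam, death_rate=mu, stop_time=t_stop,
                    condition_on_survival=True, seed=seed,
                )
            )
            estimates.append(pv.ms_rate(tree.n_tips, t_stop, eps, "crown"))
        rel_err = abs(np.mean(estimates) - r_true) / r_true
        assert rel_err < 0.15


class TestLineageTableGenerator:
    def test_zero_spread_gives_constant_rates(self):
        spec = pv.HotspotSpec(hotspot="H", n_lineages=5, rate_location=0.3, rate_spread=0.0)
        df = pv.generate_lineage_table([spec], seed=1)
        np.testing.assert_allclose(df["rate"], np.exp(0.3))

    def test_sample_mean_matches_lognormal_moment(self):
        spec = pv.HotspotSpec(
            hotspot="H", n_lineages=10_000, rate_location=0.2, rate_spread=0.4
        )
        df = pv.generate_lineage_table([spec], seed=7)
        mu, sd = 0.2, 0.4
        mean = np.exp(mu + sd**2 / 2)
        var = (np.exp(sd**2) - 1) * np.exp(2 * mu + sd**2)
        sigma = np.sqrt(var / 10_000)
        assert abs(df["rate"].mean() - mean) < 3 * sigma

    def test_highest_location_hotspot_ranks_first(self):
        # log-scale locations matching the eight published hotspot means;
        # averaging the exact fastest-lineage probabilities over independent
        # tables, the highest-location hotspot must come out on top
        means = [1.36, 1.07, 0.76, 0.73, 0.58, 0.40, 0.39, 0.14]
        specs = [
            pv.HotspotSpec(
                hotspot=f"H{i}", n_lineages=3, rate_location=float(np.log(m)),
                rate_spread=0.3,
            )
            for i, m in enumerate(means)
        ]
        acc = {f"H{i}": 0.0 for i in range(8)}
        n_tables = 15
        for seed in range(n_tables):
            table = pv.generate_lineage_table(specs, seed=seed)
            exact = pv.exact_fastest_probability(table, 1)
            assert sum(exact.values()) == pytest.approx(1.0, abs=1e-12)
            for h, p in exact.items():
                acc[h] += p / n_tables
        assert max(acc, key=acc.get) == "H0"
        # and the Monte-Carlo summary agrees on one of those tables
        table = pv.generate_lineage_table(specs, seed=0)
        exact = pv.exact_fastest_probability(table, 1)
        rs = pv.summarize(
            table,
            pv.ResamplingConfig(per_hotspot_k=1, n_samples=500, n_iterations=30, seed=0),
        )
        for _, row in rs.table.iterrows():
            assert row["prob_fastest_mean"] == pytest.approx(
                exact[row["hotspot"]], abs=0.05
            )

    def test_deterministic_per_seed_and_per_hotspot(self):
        specs = [
            pv.HotspotSpec(hotspot="A", n_lineages=4, rate_location=0.0, rate_spread=0.2),
            pv.HotspotSpec(hotspot="B", n_lineages=4, rate_location=0.5, rate_spread=0.2),
        ]
        a = pv.generate_lineage_table(specs, seed=11)
        b = pv.generate_lineage_table(specs, seed=11)
        assert a.equals(b)
        # adding a hotspot leaves earlier hotspots' draws untouched
        c = pv.generate_lineage_table(
            specs + [pv.HotspotSpec(hotspot="C", n_lineages=2, rate_location=0.0, rate_spread=0.1)],
            seed=11,
        )
        assert c[c["hotspot"] != "C"].reset_index(drop=True).equals(a)
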