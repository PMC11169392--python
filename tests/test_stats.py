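"""Rank tests (exact and asymptotic), age adjustment, twin analysis and the
exponential-plateau growth model."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rdnacn import stats
from rdnacn.stats import (age_adjust, cross_sectional_growth_correlation,
                          fit_exponential_plateau, mann_whitney,
                          spearman_correlation, stratified_correlation,
                          twin_pair_analysis, wilcoxon_signed_rank_paired)

# ---------------------------------------------------------------------------
# independent brute-force oracles (coded separately from the package paths)


def oracle_spearman_exact_p(x, y):
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    r_obs = abs(np.corrcoef(rx, ry)[0, 1])
    hits = total = 0
    for perm in itertools.permutations(range(len(y))):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= r_obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def oracle_mw_exact_p(a, b):
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1, n2 = len(a), len(b)
    mu = n1 * n2 / 2
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    hits = total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
        total += 1
    return hits / total


def oracle_wilcoxon_exact_p(x, y):
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    n = len(d)
    mu = n * (n + 1) / 4
    w_obs = ranks[d > 0].sum()
    hits = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            hits += 1
    return hits / 2 ** n


# ---------------------------------------------------------------------------


class TestSpearman:
    def test_perfect_monotone(self):
        r = spearman_correlation([1, 2, 3, 4, 5], [10, 20, 25, 40, 41])
        assert r.r == pytest.approx(1.0)

    def test_antitone(self):
        x = np.arange(6.0)
        r = spearman_correlation(x, -x)
        assert r.r == pytest.approx(-1.0)

    def test_exact_p_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            x = rng.normal(size=7)
            y = rng.normal(size=7)
            res = spearman_correlation(x, y)
            assert res.method == "exact_permutation"
            assert res.p == pytest.approx(oracle_spearman_exact_p(x, y), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = spearman_correlation(x, y)
        trans = spearman_correlation(np.exp(x), y ** 3)
        assert trans.r == pytest.approx(base.r, abs=1e-12)
        assert trans.p == pytest.approx(base.p, abs=1e-12)


class TestMannWhitney:
    def test_identical_groups_no_separation(self):
        res = mann_whitney([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert res.p >= 0.99

    def test_complete_separation_extreme_u(self):
        res = mann_whitney([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert res.u in (0.0, 25.0)

    def test_exact_p_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            a = rng.normal(size=6)
            b = rng.normal(0.5, 1, size=6)
            res = mann_whitney(a, b)
            assert res.method == "exact_enumeration"
            assert res.p == pytest.approx(oracle_mw_exact_p(a, b), abs=1e-12)

    def test_label_symmetry(self, rng):
        a = rng.normal(size=15)
        b = rng.normal(size=18)
        assert mann_whitney(a, b).p == pytest.approx(mann_whitney(b, a).p, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])


class TestWilcoxon:
    def test_all_zero_differences_error(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank_paired(x, x)

    def test_all_positive_differences_minimal_two_sided_p(self):
        """10 strictly positive differences: only the two all-same-sign
        patterns are as extreme, so exact two-sided p = 2 / 2^10."""
        x = np.arange(1.0, 11.0)
        y = x - np.linspace(0.5, 2.0, 10)
        res = wilcoxon_signed_rank_paired(x, y)
        assert res.p == pytest.approx(2 / 1024)

    def test_exact_p_matches_sign_flip_oracle(self, rng):
        for _ in range(5):
            x = rng.normal(0.4, 1, size=9)
            y = rng.normal(size=9)
            res = wilcoxon_signed_rank_paired(x, y)
            assert res.method == "exact_enumeration"
            assert res.p == pytest.approx(oracle_wilcoxon_exact_p(x, y), abs=1e-12)

    def test_antisymmetry(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        f = wilcoxon_signed_rank_paired(x, y)
        b = wilcoxon_signed_rank_paired(y, x)
        n = f.n_pairs
        assert f.w_plus + b.w_plus == pytest.approx(n * (n + 1) / 2)
        assert f.p == pytest.approx(b.p, abs=1e-12)


class TestBranchAgreement:
    def test_exact_and_asymptotic_agree_near_crossover(self, rng):
        """At the crossover sizes, mid-range exact p-values agree with the
        normal approximation to within ~10% relative error."""
        checked = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            a = r.normal(0.6, 1, size=6)
            b = r.normal(size=6)
            exact = mann_whitney(a, b)
            approx = sps.mannwhitneyu(a, b, alternative="two-sided",
                                      method="asymptotic").pvalue
            if 0.05 < exact.p < 0.7:
                assert abs(approx - exact.p) / exact.p < 0.12
                checked += 1
        assert checked >= 5


class TestAgeAdjust:
    def test_uncorrelated_age_near_identity(self, rng):
        v = rng.normal(25, 3, 200)
        age = rng.normal(50, 5, 200)
        adj = age_adjust(v, age)
        assert np.allclose(adj, v, atol=3 * np.std(v) / math.sqrt(200) * 5)

    def test_perfect_confounding_removed(self):
        age = np.array([30.0, 40.0, 50.0, 60.0])
        v = 2 * age
        adj = age_adjust(v, age)
        assert np.allclose(adj, v.mean(), atol=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        v = rng.normal(27, 4, 50)
        age = rng.normal(55, 6, 50)
        adj = age_adjust(v, age)
        # closed-form simple-regression residuals
        beta = np.cov(age, v, ddof=1)[0, 1] / np.var(age, ddof=1)
        alpha = v.mean() - beta * age.mean()
        expect = v - (alpha + beta * age) + v.mean()
        assert np.allclose(adj, expect, atol=1e-9)

    def test_constant_age_rejected(self):
        with pytest.raises(ValueError):
            age_adjust([1.0, 2.0, 3.0], [40.0, 40.0, 40.0])


class TestStratifiedCorrelation:
    def test_single_stratum_equals_pooled(self, rng):
        df = pd.DataFrame({"s": "all", "x": rng.normal(size=20),
                           "y": rng.normal(size=20)})
        rep = stratified_correlation(df, "s", "x", "y")
        assert rep.by_stratum["all"].r == pytest.approx(rep.pooled.r)

    def test_simpson_style_construction(self):
        """Opposite-signed strata can cancel in the pooled correlation."""
        x1 = np.arange(10.0)
        df = pd.DataFrame({
            "s": ["a"] * 10 + ["b"] * 10,
            "x": np.concatenate([x1, x1]),
            "y": np.concatenate([x1 + 0.1, -x1 + 0.1])})
        rep = stratified_correlation(df, "s", "x", "y")
        assert rep.by_stratum["a"].r == pytest.approx(1.0)
        assert rep.by_stratum["b"].r == pytest.approx(-1.0)
        assert abs(rep.pooled.r) < 0.3

    def test_small_stratum_skipped(self, rng):
        df = pd.DataFrame({"s": ["a"] * 10 + ["b"] * 2,
                           "x": rng.normal(size=12), "y": rng.normal(size=12)})
        rep = stratified_correlation(df, "s", "x", "y")
        assert rep.skipped == ("b",) and "b" not in rep.by_stratum

    def test_nulled_stratum_recovered(self):
        """A stratum with the effect switched off shows near-zero correlation
        while the active stratum retains the generative negative slope."""
        from rdnacn.simulate import SimulationConfig, simulate_cohort
        cfg = SimulationConfig(n_samples=400, bmi_cn_effect=-0.5,
                               bmi_cn_effect_medicated=0.0, n_exome_bases=1000,
                               n_cpgs=10)
        sim = simulate_cohort(cfg, seed=77)
        df = sim.phenotypes.merge(sim.truth, on="sample_id")
        rep = stratified_correlation(df, "medicated", "cn_true", "bmi")
        assert rep.by_stratum["non_medicated"].r < -0.3
        assert abs(rep.by_stratum["medicated"].r) < 0.2


class TestTwins:
    def test_shared_cn_reported_as_undetectable(self):
        rows = []
        for i in range(6):
            for role, bmi in (("heavier", 28 + i), ("leaner", 24 + i)):
                rows.append({"sample_id": f"p{i}{role}", "twin_pair_id": f"p{i}",
                             "bmi": bmi, "cn": 400 + 10 * i, "methylation": 0.3,
                             "age": 30 + i})
        rep = twin_pair_analysis(pd.DataFrame(rows))
        assert rep.paired_tests["cn"] is None
        assert "no difference detectable" in rep.notes["cn"]
        assert rep.paired_tests["bmi"].p < 0.05

    def test_incomplete_pair_rejected(self):
        df = pd.DataFrame([{"sample_id": "a", "twin_pair_id": "p0", "bmi": 25,
                            "cn": 400, "methylation": 0.3, "age": 30}])
        with pytest.raises(ValueError, match="exactly 2"):
            twin_pair_analysis(df)

    def test_discordant_bmi_power(self):
        """Simulated 3 kg/m^2 discordance at 24 pairs: the paired BMI test is
        significant in >= 80% of 100 cohorts, while the shared-CN test stays
        non-significant in >= 85%."""
        from rdnacn.simulate import TwinConfig, simulate_twins
        bmi_sig = cn_nonsig = 0
        reps = 100
        for i in range(reps):
            records, _ = simulate_twins(TwinConfig(), seed=10_000 + i)
            rep = twin_pair_analysis(records)
            bmi_sig += rep.paired_tests["bmi"].p < 0.05
            cn_nonsig += rep.paired_tests["cn"].p > 0.05
        assert bmi_sig / reps >= 0.8
        assert cn_nonsig / reps >= 0.85


class TestPlateauFit:
    def test_noise_free_recovery(self):
        t = np.arange(0, 12, dtype=float)
        w = 300 - (300 - 150) * np.exp(-0.3 * t)
        fit = fit_exponential_plateau(t, w)
        assert fit.ym == pytest.approx(300, abs=1e-6)
        assert fit.y0 == pytest.approx(150, abs=1e-6)
        assert fit.k == pytest.approx(0.3, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_exponential_plateau(np.arange(5.0), np.full(5, 200.0))

    def test_first_order_optimality(self, rng):
        """At the optimum, residuals are orthogonal to the model gradient."""
        t = np.arange(0.0, 12.0)
        w = 260 - 90 * np.exp(-0.4 * t) + rng.normal(0, 2, 12)
        fit = fit_exponential_plateau(t, w)
        resid = w - fit.predict(t)
        ek = np.exp(-fit.k * t)
        grad = np.column_stack([
            1 - ek,  # d/dYM
            ek,  # d/dY0
            (fit.ym - fit.y0) * t * ek,  # d/dk
        ])
        score = grad.T @ resid
        assert np.all(np.abs(score) < 1e-3 * max(1.0, np.abs(resid).sum()))

    def test_deterministic(self, rng):
        t = np.arange(0.0, 12.0)
        w = 260 - 90 * np.exp(-0.4 * t) + rng.normal(0, 3, 12)
        f1 = fit_exponential_plateau(t, w)
        f2 = fit_exponential_plateau(t, w)
        assert (f1.ym, f1.y0, f1.k) == (f2.ym, f2.y0, f2.k)


class TestGrowthCorrelation:
    def _weights(self, table):
        rows = []
        for sid, series in table.items():
            for wk, wt in series.items():
                rows.append({"sample_id": sid, "week": wk, "weight": wt})
        return pd.DataFrame(rows)

    def test_gain_correlation_matches_manual_recomputation(self):
        """5-animal fixture: gain correlation equals Spearman of
        (last - first) weights vs CN recomputed by hand."""
        weights = self._weights({
            "a": {8: 100, 19: 200}, "b": {8: 110, 19: 180},
            "c": {8: 105, 19: 240}, "d": {8: 95, 19: 160},
            "e": {8: 120, 19: 210}})
        cn = {"a": 300, "b": 420, "c": 250, "d": 500, "e": 380}
        rep = cross_sectional_growth_correlation(weights, cn)
        gains = {s: weights[(weights.sample_id == s) & (weights.week == 19)].weight.iloc[0]
                 - weights[(weights.sample_id == s) & (weights.week == 8)].weight.iloc[0]
                 for s in cn}
        ids = sorted(cn)
        expect = spearman_correlation([gains[s] for s in ids], [cn[s] for s in ids])
        assert rep.gain.r == pytest.approx(expect.r, abs=1e-12)
        assert rep.gain.p == pytest.approx(expect.p, abs=1e-12)

    def test_missing_endpoint_rejected(self):
        weights = self._weights({"a": {8: 100, 19: 200}, "b": {8: 100}})
        with pytest.raises(ValueError, match="missing"):
            cross_sectional_growth_correlation(weights, {"a": 300, "b": 400})

    def test_null_effect_gives_flat_profile(self):
        from rdnacn.simulate import GrowthConfig, simulate_growth
        weights, truth = simulate_growth(GrowthConfig(gain_cn_effect=0.0), seed=5)
        rep = cross_sectional_growth_correlation(
            weights, dict(zip(truth.sample_id, truth.cn_obs)))
        assert rep.per_week["r"].abs().max() < 0.45  # sampling noise only
        assert (rep.per_week["p"] < 0.05).mean() < 0.5
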