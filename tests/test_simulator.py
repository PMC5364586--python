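"""The copy-number-aware plasma simulator: categorical CNA model, burden and
bias adjustments, Poisson/binomial count generation, determinism."""

import dataclasses

import numpy as np
import pytest

from ctorigin.io import ArrayProfile
from ctorigin.simulator import (
    DEFAULT_CNA_PROBS,
    CnaModel,
    SimScenario,
    adjust_bias,
    adjust_theta,
    cna_preset,
    default_bias,
    sample_copy_numbers,
    simulate_cancer_plasma,
    simulate_normal_plasma,
)


class TestCnaModel:
    def test_default_probabilities_have_exact_moments(self):
        m = CnaModel()
        assert sum(m.probs) == pytest.approx(1.0, abs=1e-12)
        assert m.mean_copy_number == pytest.approx(2.0, abs=1e-12)
        assert m.cna_rate == pytest.approx(0.30, abs=1e-12)

    @pytest.mark.parametrize("rate", [0.1, 0.3, 0.5])
    def test_presets_preserve_both_moment_constraints(self, rate):
        m = cna_preset(rate)
        assert m.cna_rate == pytest.approx(rate, abs=1e-12)
        assert sum(m.probs) == pytest.approx(1.0, abs=1e-12)
        assert m.mean_copy_number == pytest.approx(2.0, abs=1e-12)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            CnaModel((0.5, 0.5, 0, 0, 0, 0))  # mean 0.5, not 2
        with pytest.raises(ValueError):
            CnaModel((0.1, 0.1, 0.1, 0.1, 0.1, 0.1))  # sums to 0.6

    def test_degenerate_diploid_only(self, rng):
        c = sample_copy_numbers(CnaModel((0, 0, 1, 0, 0, 0)), 1000, rng)
        assert np.all(c == 2)

    def test_empirical_rate_and_mean(self, rng):
        K = 100_000
        c = sample_copy_numbers(CnaModel(), K, rng)
        rate = float(np.mean(c != 2))
        se_rate = np.sqrt(0.3 * 0.7 / K)
        assert abs(rate - 0.30) <= 3 * se_rate
        mean_c = float(np.mean(c))
        se_mean = float(np.std(c) / np.sqrt(K))
        assert abs(mean_c - 2.0) <= 3 * se_mean


class TestAdjustments:
    @pytest.mark.parametrize(
        "theta,c,expected",
        [(0.2, 2, 0.2), (0.2, 4, 1.0 / 3.0), (0.5, 0, 0.0), (0.0, 5, 0.0), (1.0, 3, 1.0)],
    )
    def test_theta_prime_formula(self, theta, c, expected):
        assert adjust_theta(theta, c) == pytest.approx(expected)

    def test_theta_prime_increasing_in_copy_number(self):
        for theta in (0.1, 0.5, 0.9):
            vals = [adjust_theta(theta, c) for c in range(6)]
            assert all(b > a for a, b in zip(vals, vals[1:]))
            assert all(0.0 <= v <= 1.0 for v in vals)

    def test_bias_unchanged_when_diploid_or_theta_zero(self, rng):
        b = rng.dirichlet(np.ones(30))
        assert adjust_bias(b, 0.7, np.full(30, 2)) == pytest.approx(b)
        assert adjust_bias(b, 0.0, rng.integers(0, 6, 30)) == pytest.approx(b)

    def test_bias_matches_formula_term_by_term(self, rng):
        b = rng.dirichlet(np.ones(50))
        theta = 0.37
        c = rng.integers(0, 6, 50)
        B = adjust_bias(b, theta, c)
        w = b * (1 - theta + theta * c / 2)
        assert B == pytest.approx(w / w.sum())
        assert B.sum() == pytest.approx(1.0, abs=1e-12)

    def test_expected_tumor_read_fraction_equals_theta(self, rng):
        # with uniform bias, sum_k B_k * theta'_k should average to theta
        K = 5000
        b = np.full(K, 1.0 / K)
        for theta in (0.2, 0.6):
            c = sample_copy_numbers(CnaModel(), K, rng)
            B = adjust_bias(b, theta, c)
            tumor_frac = float(np.sum(B * adjust_theta(theta, c)))
            assert tumor_frac == pytest.approx(theta, abs=0.01)


def make_scenario(levels_normal, levels_tumor, Z=50_000, theta_range=(0.0, 1.0)):
    cids = list(levels_normal[0])
    bias = {cid: 1.0 / len(cids) for cid in cids}
    normal_pool = [ArrayProfile(f"n{i}", 0, lv) for i, lv in enumerate(levels_normal)]
    tumor_pool = [ArrayProfile(f"t{i}", 1, lv) for i, lv in enumerate(levels_tumor)]
    return SimScenario(theta_range, Z, bias, CnaModel(), normal_pool, {1: tumor_pool})


@pytest.fixture()
def toy_scenario(rng):
    cids = [f"c{i}" for i in range(40)]
    v = {cid: float(x) for cid, x in zip(cids, rng.uniform(0.05, 0.95, 40))}
    u = {cid: float(x) for cid, x in zip(cids, rng.uniform(0.05, 0.95, 40))}
    v2 = {cid: min(1.0, x + 0.01) for cid, x in v.items()}
    return make_scenario([v, v2], [u])


class TestSimulateCancer:
    def test_pure_normal_limit(self, toy_scenario, rng):
        scen = dataclasses.replace(toy_scenario, theta_range=(0.0, 0.0))
        prof, truth = simulate_cancer_plasma(scen, 1, rng)
        v = scen.normal_pool[0].levels if truth["normal_sample"] == "n0" else scen.normal_pool[1].levels
        ratios = np.array([m / n for m, n in prof.counts.values() if n > 0])
        vv = np.array([v[cid] for cid, (m, n) in prof.counts.items() if n > 0])
        # each cluster has ~Z/K = 1250 reads: binomial noise ~ 0.014
        assert np.mean(np.abs(ratios - vv)) < 0.02

    def test_pure_tumor_limit_without_cna(self, toy_scenario, rng):
        scen = dataclasses.replace(
            toy_scenario, theta_range=(1.0, 1.0), cna=CnaModel((0, 0, 1, 0, 0, 0))
        )
        prof, truth = simulate_cancer_plasma(scen, 1, rng)
        u = scen.tumor_pools[1][0].levels
        ratios = np.array([m / n for m, n in prof.counts.values() if n > 0])
        uu = np.array([u[cid] for cid, (m, n) in prof.counts.items() if n > 0])
        assert np.mean(np.abs(ratios - uu)) < 0.02

    def test_counts_valid_and_ratio_converges_to_x(self, toy_scenario):
        # fixed sources and theta: mean m/n over replicates approaches x_k
        scen = dataclasses.replace(
            toy_scenario, theta_range=(0.4, 0.4), cna=CnaModel((0, 0, 1, 0, 0, 0)), Z=4000
        )
        sums: dict[str, list] = {}
        rng = np.random.default_rng(99)
        for i in range(300):
            prof, truth = simulate_cancer_plasma(scen, 1, rng)
            if truth["normal_sample"] != "n0":
                continue
            for cid, (m, n) in prof.counts.items():
                sums.setdefault(cid, []).append((m, n))
        v = scen.normal_pool[0].levels
        u = scen.tumor_pools[1][0].levels
        for cid, pairs in sums.items():
            m_tot = sum(m for m, _ in pairs)
            n_tot = sum(n for _, n in pairs)
            x = 0.6 * v[cid] + 0.4 * u[cid]
            assert 0 <= m_tot <= n_tot
            se = np.sqrt(max(x * (1 - x), 1e-4) / max(n_tot, 1))
            assert abs(m_tot / n_tot - x) <= 4 * se

    def test_na_clusters_dropped_and_recorded(self, toy_scenario, rng):
        scen = toy_scenario
        for p in scen.normal_pool:
            p.levels["c0"] = float("nan")
        prof, truth = simulate_cancer_plasma(scen, 1, rng)
        assert "c0" not in prof.counts
        assert "c0" in truth["dropped"]

    def test_seeded_run_reproducible(self, toy_scenario):
        p1, t1 = simulate_cancer_plasma(toy_scenario, 1, np.random.default_rng(5))
        p2, t2 = simulate_cancer_plasma(toy_scenario, 1, np.random.default_rng(5))
        assert p1.counts == p2.counts
        assert t1["theta"] == t2["theta"]
        assert np.array_equal(t1["copy_numbers"], t2["copy_numbers"])

    def test_empty_or_missing_pool_rejected(self, toy_scenario, rng):
        with pytest.raises(ValueError):
            simulate_cancer_plasma(toy_scenario, 2, rng)
        scen = dataclasses.replace(toy_scenario, normal_pool=[])
        with pytest.raises(ValueError):
            simulate_cancer_plasma(scen, 1, rng)


class TestSimulateNormal:
    def test_ratio_zero_uses_first_profile_only(self, toy_scenario):
        rng = np.random.default_rng(3)
        prof, truth = simulate_normal_plasma(toy_scenario, rng, ratio=0.0)
        first = next(
            p for p in toy_scenario.normal_pool if p.sample_id == truth["normal_samples"][0]
        )
        ratios = {cid: m / n for cid, (m, n) in prof.counts.items() if n > 100}
        for cid, r in ratios.items():
            assert abs(r - first.levels[cid]) < 0.05

    def test_identical_pool_members_give_their_level(self, rng):
        cids = [f"c{i}" for i in range(20)]
        lv = {cid: 0.42 for cid in cids}
        scen = make_scenario([dict(lv), dict(lv)], [dict(lv)], Z=200_000)
        prof, _ = simulate_normal_plasma(scen, rng)
        for cid, (m, n) in prof.counts.items():
            if n > 1000:
                assert m / n == pytest.approx(0.42, abs=0.02)

    def test_seeded_run_reproducible(self, toy_scenario):
        p1, _ = simulate_normal_plasma(toy_scenario, np.random.default_rng(8))
        p2, _ = simulate_normal_plasma(toy_scenario, np.random.default_rng(8))
        assert p1.counts == p2.counts

    def test_needs_two_pool_samples(self, toy_scenario, rng):
        scen = dataclasses.replace(toy_scenario, normal_pool=toy_scenario.normal_pool[:1])
        with pytest.raises(ValueError):
            simulate_normal_plasma(scen, rng)


def test_default_bias_proportional_to_site_count(small_ref):
    bias = default_bias(small_ref.clusters)
    total_sites = sum(c.site_count for c in small_ref.clusters)
    assert sum(bias.values()) == pytest.approx(1.0, abs=1e-9)
    for c in small_ref.clusters[:20]:
        assert bias[c.cluster_id] == pytest.approx(c.site_count / total_sites)


def test_default_bias_dirichlet_perturbation_keeps_simplex(small_ref, rng):
    bias = default_bias(small_ref.clusters, rng=rng, dirichlet_conc=50.0)
    vals = np.array(list(bias.values()))
    assert vals.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(vals >= 0)
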