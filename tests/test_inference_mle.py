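"""Grid-search MLE over (theta, t), the lambda score, and the cancer call."""

import dataclasses

import numpy as np
import pytest

from ctorigin.inference import (
    InferenceError,
    PanelLikelihood,
    ThetaGrid,
    grid_mle,
    predict_many,
    total_loglik,
)
from ctorigin.io import SeqProfile
from ctorigin.simulator import (
    SimScenario,
    cna_preset,
    default_bias,
    simulate_cancer_plasma,
    simulate_normal_plasma,
)


@pytest.fixture(scope="module")
def scenario(small_ref):
    return SimScenario(
        theta_range=(0.0, 1.0),
        Z=4 * small_ref.config.K_total,
        bias=default_bias(small_ref.clusters),
        cna=cna_preset(0.3),
        normal_pool=small_ref.pools_by_class()[0],
        tumor_pools={t: small_ref.pools_by_class()[t] for t in range(1, 4)},
    )


@pytest.fixture(scope="module")
def engine(small_panel):
    return PanelLikelihood(small_panel, ThetaGrid(100))


class TestThetaGrid:
    def test_contains_zero_and_is_increasing(self):
        g = ThetaGrid(100).values
        assert g.size == 100 and g[0] == 0.0
        assert np.all(np.diff(g) > 0) and g[-1] < 1.0

    def test_too_coarse_rejected(self):
        with pytest.raises(ValueError):
            ThetaGrid(1)


class TestTotalLoglik:
    def test_single_cluster_profile_equals_cluster_marginal(self, small_panel):
        cid = small_panel.selected_features[0]
        prof = SeqProfile("s", {cid: (3, 8)})
        from ctorigin.inference import cluster_loglik

        expected = cluster_loglik(
            3, 8, 0.4, small_panel.models[0].params[cid], small_panel.models[1].params[cid]
        )
        got = total_loglik(prof, small_panel, 0.4, 1)
        assert got == pytest.approx(expected, abs=1e-4)

    def test_duplicating_clusters_doubles_loglik(self, small_panel):
        feats = small_panel.selected_features[:10]
        single = SeqProfile("a", {cid: (2, 6) for cid in feats})
        ll = total_loglik(single, small_panel, 0.3, 2)
        assert total_loglik(single, small_panel, 0.3, 2) == pytest.approx(ll)
        # doubling the feature set doubles the sum (independence)
        ll_each = [
            total_loglik(SeqProfile("b", {cid: (2, 6)}), small_panel, 0.3, 2)
            for cid in feats
        ]
        assert ll == pytest.approx(sum(ll_each), rel=1e-9)

    def test_theta_zero_is_class_independent(self, small_panel, rng):
        feats = small_panel.selected_features[:20]
        prof = SeqProfile(
            "s", {cid: (int(rng.integers(0, 5)), 6) for cid in feats}
        )
        lls = [total_loglik(prof, small_panel, 0.0, t) for t in (1, 2, 3)]
        assert lls[0] == pytest.approx(lls[1], abs=1e-9)
        assert lls[0] == pytest.approx(lls[2], abs=1e-9)


class TestGridMLE:
    def test_pure_normal_sample_is_not_called_cancer(self, small_panel, scenario, engine, rng):
        for i in range(5):
            prof, _ = simulate_normal_plasma(scenario, rng, f"n{i}")
            res = grid_mle(prof, small_panel, engine=engine)
            assert res.lambda_score >= 0.0
            assert res.lambda_score < 0.023
            assert not res.is_cancer
            assert res.predicted_label == 0

    def test_recovers_burden_and_class(self, small_panel, scenario, engine, rng):
        scen = dataclasses.replace(
            scenario, theta_range=(0.4, 0.4), Z=50 * small_ref_K(scenario)
        )
        prof, truth = simulate_cancer_plasma(scen, 2, rng, "c")
        res = grid_mle(prof, small_panel, engine=engine)
        assert res.is_cancer
        assert res.t_hat == 2
        assert abs(res.theta_hat - 0.4) <= 0.05

    def test_lambda_zero_iff_argmax_at_theta_zero(self, small_panel, engine, scenario, rng):
        for i in range(10):
            prof, _ = simulate_normal_plasma(scenario, rng, f"z{i}")
            res = grid_mle(prof, small_panel, engine=engine)
            if res.theta_hat == 0.0:
                assert res.lambda_score == 0.0
                assert res.t_hat is None

    def test_no_usable_features_is_an_error(self, small_panel, engine):
        empty = SeqProfile("empty", {})
        with pytest.raises(InferenceError):
            grid_mle(empty, small_panel, engine=engine)
        zeroed = SeqProfile(
            "zeroed", {cid: (0, 0) for cid in small_panel.selected_features}
        )
        with pytest.raises(InferenceError):
            grid_mle(zeroed, small_panel, engine=engine)

    def test_deterministic(self, small_panel, scenario, engine, rng):
        prof, _ = simulate_cancer_plasma(scenario, 1, rng, "d")
        r1 = grid_mle(prof, small_panel, engine=engine)
        r2 = grid_mle(prof, small_panel, engine=engine)
        assert r1.theta_hat == r2.theta_hat
        assert r1.t_hat == r2.t_hat
        assert r1.lambda_score == r2.lambda_score
        assert np.array_equal(r1.loglik_grid, r2.loglik_grid)

    def test_median_error_shrinks_with_coverage(self, small_ref, small_panel, scenario):
        # low coverages: past ~20 cytosines/cluster the median error
        # saturates at the theta-grid resolution
        medians = []
        for cov in (1, 4, 16):
            rng = np.random.default_rng(5150)
            scen = dataclasses.replace(scenario, Z=cov * small_ref.config.K_total)
            errs = []
            engine = PanelLikelihood(small_panel, ThetaGrid(100))
            for i in range(30):
                t = 1 + i % 3
                prof, truth = simulate_cancer_plasma(scen, t, rng, f"m{i}")
                res = grid_mle(prof, small_panel, engine=engine)
                errs.append(abs(res.theta_hat - truth["theta"]))
            medians.append(float(np.median(errs)))
        assert medians[0] > medians[1] > medians[2]

    def test_burden_recovery_pcc(self, small_ref, small_panel, scenario):
        """Over 200 simulated cancer profiles with theta ~ U(0,1), the
        estimated burden correlates with truth at PCC >= 0.97."""
        rng = np.random.default_rng(2718)
        engine = PanelLikelihood(small_panel, ThetaGrid(100))
        true_t, est_t = [], []
        for i in range(200):
            t = 1 + i % 3
            prof, truth = simulate_cancer_plasma(scenario, t, rng, f"p{i}")
            res = grid_mle(prof, small_panel, engine=engine)
            true_t.append(truth["theta"])
            est_t.append(res.theta_hat)
        pcc = float(np.corrcoef(true_t, est_t)[0, 1])
        assert pcc >= 0.97


def small_ref_K(scenario):
    return len(scenario.bias)
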