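"""Summary statistics, rejection sampling, model choice and posterior
adjustment."""

import numpy as np
import pandas as pd
import pytest

from hyborigin import (
    GenotypeMatrix,
    estimate_posterior,
    model_check_pca,
    model_choice_direct,
    model_choice_logistic,
    panel_summary_stats,
    rejection_select,
    stat_names,
    summary_stats,
)
from hyborigin.abc import _admix_f

from _oracles import (
    nei_bruteforce,
    pca_bruteforce,
    rejection_bruteforce,
    wc_theta_bruteforce,
)


def _matrix(dosage, pops):
    dosage = np.asarray(dosage, dtype=np.int8)
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(dosage.shape[0])],
        pop_labels=list(pops),
        locus_ids=[f"L{j}" for j in range(dosage.shape[1])],
        dosage=dosage,
    )


class TestSummaryStats:
    def test_admixture_estimator_identities(self, rng):
        p1 = rng.uniform(0.1, 0.9, 30)
        p2 = rng.uniform(0.1, 0.9, 30)
        assert _admix_f(p1, p1, p2) == pytest.approx(1.0)
        assert _admix_f(p2, p1, p2) == pytest.approx(0.0)
        w = 0.68
        assert _admix_f(w * p1 + (1 - w) * p2, p1, p2) == pytest.approx(w)

    def test_names_and_length(self):
        names = stat_names(["a", "b", "c"], [("c", "a", "b")])
        assert len(names) == 3 + 3 + 3 + 3 + 1
        assert names[0] == "gene_div_a"
        assert names[-1] == "admix_f_c_a_b"

    def test_three_group_toy_matches_hand_oracle(self, rng):
        """Full vector against literal per-statistic recomputation."""
        dosage = rng.integers(0, 3, size=(12, 4)).astype(np.int8)
        pops = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        g = _matrix(dosage, pops)
        got = panel_summary_stats(g, ["a", "b", "c"], [("c", "a", "b")])
        names = stat_names(["a", "b", "c"], [("c", "a", "b")])
        blocks = {p: dosage[np.array(pops) == p] for p in "abc"}
        freqs = {p: blocks[p].sum(axis=0) / (2 * 4) for p in "abc"}
        expected = []
        for p in "abc":  # gene diversity with 2n/(2n-1)
            f = freqs[p]
            expected.append(float(np.mean(8 / 7 * 2 * f * (1 - f))))
        for p in "abc":  # monomorphic proportion
            f = freqs[p]
            expected.append(float(np.mean((f == 0) | (f == 1))))
        for x, y in (("a", "b"), ("a", "c"), ("b", "c")):
            expected.append(wc_theta_bruteforce([blocks[x], blocks[y]]))
        for x, y in (("a", "b"), ("a", "c"), ("b", "c")):
            expected.append(nei_bruteforce(freqs[x], freqs[y]))
        den = float(np.sum((freqs["a"] - freqs["b"]) ** 2))
        expected.append(
            float(np.sum((freqs["c"] - freqs["b"]) * (freqs["a"] - freqs["b"])) / den)
        )
        np.testing.assert_allclose(got, expected, atol=1e-12)
        assert list(summary_stats(g, admixed_specs=[("c", "a", "b")]).index) == names

    def test_unknown_group_is_error(self, admixed_panel):
        with pytest.raises(Exception, match="unknown population"):
            panel_summary_stats(admixed_panel, ["parent_a", "nope"], [])


class TestRejection:
    def test_fraction_one_returns_everything(self, rng):
        ref = rng.normal(size=(25, 4))
        sel = rejection_select(ref, ref[3], 1.0)
        assert len(sel.indices) == 25

    def test_observed_row_ranks_first_with_zero_distance(self, rng):
        ref = rng.normal(size=(40, 5))
        sel = rejection_select(ref, ref[17], 0.1)
        assert sel.indices[0] == 17
        assert sel.distances[0] == 0.0

    def test_ten_row_toy_matches_bruteforce(self, rng):
        ref = rng.normal(size=(10, 3))
        obs = rng.normal(size=3)
        sel = rejection_select(ref, obs, 0.5)
        idx, dists = rejection_bruteforce(ref, obs, 0.5)
        assert list(sel.indices) == idx
        np.testing.assert_allclose(sel.distances, dists, atol=1e-9)

    def test_zero_variance_stat_excluded_with_warning(self, rng):
        ref = rng.normal(size=(30, 3))
        ref[:, 1] = 4.2
        with pytest.warns(UserWarning, match="zero-variance"):
            sel = rejection_select(ref, np.zeros(3), 0.5)
        assert sel.dropped_stats == ["s1"]

    def test_bad_fraction_rejected(self, rng):
        with pytest.raises(ValueError):
            rejection_select(rng.normal(size=(5, 2)), np.zeros(2), 0.0)


class TestModelChoiceDirect:
    def test_unanimous(self):
        res = model_choice_direct(np.ones(600, dtype=int), 500)
        assert res.probabilities == {1: 1.0}

    def test_vote_shares(self):
        labels = np.array([1] * 300 + [2] * 200)
        res = model_choice_direct(labels, 500)
        assert res.probabilities == {1: 0.6, 2: 0.4}

    def test_toy_equals_hand_count(self, rng):
        labels = rng.integers(1, 4, size=50)
        res = model_choice_direct(labels, 20)
        top = labels[:20]
        for s in (1, 2, 3):
            assert res.probabilities[s] == pytest.approx((top == s).sum() / 20)

    def test_k_larger_than_rows_is_error(self):
        with pytest.raises(ValueError):
            model_choice_direct(np.ones(10, dtype=int), 11)


class TestModelChoiceLogistic:
    def test_identical_distributions_give_half_half(self, rng):
        stats = rng.normal(size=(600, 4))
        labels = np.array([1, 2] * 300)
        res = model_choice_logistic(stats, labels, np.zeros(4))
        assert res.probabilities[1] == pytest.approx(0.5, abs=0.08)
        assert res.probabilities[2] == pytest.approx(0.5, abs=0.08)
        if res.ci is not None:
            lo, hi = res.ci[1]
            assert lo <= 0.5 <= hi

    def test_separable_fixture_prefers_closer_scenario(self, rng):
        # scenario 1 occupies stat < 0 side, scenario 2 stat > 1; obs at 0
        x1 = rng.uniform(-1.0, 0.1, size=(200, 1))
        x2 = rng.uniform(0.9, 2.0, size=(200, 1))
        stats = np.vstack([x1, x2])
        labels = np.array([1] * 200 + [2] * 200)
        res = model_choice_logistic(stats, labels, np.zeros(1))
        assert res.probabilities[1] > 0.95

    def test_agrees_with_direct_on_well_mixed_table(self, rng):
        # two overlapping clouds; probabilities should broadly agree
        n = 400
        stats = np.vstack(
            [rng.normal(-0.3, 1.0, size=(n, 2)), rng.normal(0.3, 1.0, size=(n, 2))]
        )
        labels = np.array([1] * n + [2] * n)
        d = np.sqrt((stats**2).sum(axis=1))
        order = np.argsort(d, kind="stable")
        res_l = model_choice_logistic(stats[order], labels[order], np.zeros(2))
        res_d = model_choice_direct(labels[order], 200)
        assert res_l.probabilities[1] == pytest.approx(
            res_d.probabilities[1], abs=0.1
        )

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            model_choice_logistic(np.zeros((10, 2)), np.ones(10), np.zeros(2))

    def test_rejection_fraction_one_recovers_uniform_prior(self, rng):
        """With all rows accepted, both model-choice routes fall back to
        the (uniform) scenario prior."""
        n = 500
        stats = rng.normal(size=(3 * n, 3))
        labels = np.repeat([1, 2, 3], n)
        perm = rng.permutation(3 * n)
        stats, labels = stats[perm], labels[perm]
        sel = rejection_select(stats, np.zeros(3), 1.0)
        res_d = model_choice_direct(labels[sel.indices], len(labels))
        res_l = model_choice_logistic(
            stats[sel.indices], labels[sel.indices], np.zeros(3)
        )
        for s in (1, 2, 3):
            assert res_d.probabilities[s] == pytest.approx(1 / 3, abs=0.01)
            assert res_l.probabilities[s] == pytest.approx(1 / 3, abs=0.08)


class TestEstimatePosterior:
    def test_null_regression_returns_accepted_sample(self, rng):
        """Stats constructed orthogonal to the parameter leave the sample
        unadjusted."""
        n = 40
        x = np.concatenate([rng.uniform(-1, 1, n // 2)] * 2)
        x[n // 2 :] *= -1  # +/- pairs with equal weights
        theta = np.tile(rng.uniform(20, 80, n // 2), 2)
        dist = np.tile(rng.uniform(0.1, 1.0, n // 2), 2)
        params = pd.DataFrame({"N1": theta})
        post = estimate_posterior(
            params, x[:, None], dist, np.zeros(1), {"N1": (10.0, 100.0)}
        )
        np.testing.assert_allclose(post["N1"].sample, theta, rtol=1e-9)
        assert post["N1"].median == pytest.approx(np.median(theta))

    def test_noiseless_linear_map_recovers_truth_exactly(self, rng):
        """Parameter whose logit is a linear function of the statistic is
        adjusted exactly onto the truth."""
        lo, hi = 10.0, 1000.0
        c = 0.7
        s_obs = 0.3
        s = rng.uniform(-2, 2, 60)
        z = c * s
        theta = lo + (hi - lo) / (1 + np.exp(-z))
        params = pd.DataFrame({"t1": theta})
        dist = np.abs(s - s_obs)
        post = estimate_posterior(
            params, s[:, None], dist, np.array([s_obs]), {"t1": (lo, hi)}
        )
        truth = lo + (hi - lo) / (1 + np.exp(-c * s_obs))
        np.testing.assert_allclose(post["t1"].sample, truth, rtol=1e-6)

    def test_adjusted_values_stay_inside_prior_bounds(self, rng):
        n = 50
        s = rng.uniform(-1, 1, n)
        theta = np.clip(500 + 400 * s + rng.normal(0, 10, n), 10, 999)
        params = pd.DataFrame({"Na": theta})
        # obs far outside the accepted cloud forces extreme extrapolation
        post = estimate_posterior(
            params, s[:, None], np.abs(s - 30), np.array([30.0]),
            {"Na": (10.0, 1000.0)},
        )
        assert (post["Na"].sample >= 10.0).all()
        assert (post["Na"].sample <= 1000.0).all()

    def test_requires_twenty_rows(self, rng):
        with pytest.raises(ValueError):
            estimate_posterior(
                pd.DataFrame({"N1": np.ones(5)}),
                rng.normal(size=(5, 1)),
                np.ones(5),
                np.zeros(1),
                {"N1": (0.0, 2.0)},
            )


class TestModelCheckPca:
    def test_mean_vector_projects_to_origin(self, rng):
        ref = rng.normal(size=(200, 6))
        out = model_check_pca(ref, None, ref.mean(axis=0))
        np.testing.assert_allclose(out["observed"], 0.0, atol=1e-9)

    def test_component_variances_equal_eigenvalues(self, rng):
        ref = rng.normal(size=(300, 5)) @ rng.normal(size=(5, 5))
        out = model_check_pca(ref, None, ref[0], n_components=5)
        proj_var = out["reference"].var(axis=0, ddof=1)
        np.testing.assert_allclose(proj_var, out["explained_variance"], rtol=1e-8)

    def test_three_stat_toy_matches_eigh_oracle(self, rng):
        ref = rng.normal(size=(100, 3)) * np.array([3.0, 1.0, 0.2])
        out = model_check_pca(ref, ref[:5], ref[0], n_components=3)
        mu, sd = ref.mean(0), ref.std(0)
        Z = (ref - mu) / sd
        vals, vecs = pca_bruteforce(Z)
        np.testing.assert_allclose(out["explained_variance"], vals, rtol=1e-8)
        # components match up to sign
        for i in range(3):
            dot = abs(np.dot(out["components"][i], vecs[:, i]))
            assert dot == pytest.approx(1.0, abs=1e-8)
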