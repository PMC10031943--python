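"""Scenario registry, validation, priors and the coalescent SNP simulator."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency, kstest

import hyborigin as hb
from hyborigin import (
    Event,
    PriorSet,
    Scenario,
    ScenarioError,
    draw_parameters,
    hybrid_origin_scenarios,
    simulate_snp_panel,
    validate_scenario,
    weir_cockerham_theta,
)


class TestScenarioRegistry:
    def test_exactly_ten_valid_scenarios(self):
        scen = hybrid_origin_scenarios()
        assert len(scen) == 10
        assert [s.scenario_id for s in scen] == list(range(1, 11))
        for s in scen:
            assert validate_scenario(s) == []

    def test_scenario_one_structure(self):
        s1 = hybrid_origin_scenarios()[0]
        assert s1.n_admixture_events == 2
        admixes = [e for e in s1.events if e.kind == "admix"]
        targets = {e.target for e in admixes}
        assert targets == {hb.PTILOSPERMA, hb.NG_LINEAGE}
        for e in admixes:
            assert {e.source_a, e.source_b} == {hb.MICRANTHA, hb.FLAVIDA}

    def test_single_origin_scenarios_have_one_admixture_and_one_split(self):
        scen = {s.scenario_id: s for s in hybrid_origin_scenarios()}
        for sid in (7, 8):
            s = scen[sid]
            assert s.n_admixture_events == 1
            # the focal lineages split from the hybrid lineage before it forms
            merge, admix = s.events[0], s.events[1]
            assert merge.kind == "merge"
            assert admix.kind == "admix"
            assert merge.source_a == admix.target

    def test_every_scenario_coalesces_in_simulation(self):
        sizes = {p: 3 for p in hb.SAMPLED_POPULATIONS}
        priors = PriorSet()
        for s in hybrid_origin_scenarios():
            rng = np.random.default_rng(s.scenario_id)
            draw = draw_parameters(s, priors, rng)
            panel = simulate_snp_panel(s, draw, sizes, 5, seed=7, maf_min=0.0)
            assert panel.dosage.shape == (12, 5)
            # every locus is variant (one mutation each)
            counts = panel.dosage.sum(axis=0)
            assert ((counts > 0) & (counts < 24)).all()


class TestValidateScenario:
    def test_event_on_removed_population(self):
        s = Scenario(
            99,
            ("a", "b", "c"),
            (
                Event("merge", 40.0, "a", "b"),
                Event("admix", 50.0, "a", "b", "c", 0.5),
                Event("merge", 60.0, "b", "c"),
            ),
            {"a": 100.0, "b": 100.0, "c": 100.0},
        )
        assert any("no longer exists" in v for v in validate_scenario(s))

    def test_valid_two_population_split(self):
        s = Scenario(
            99,
            ("a", "b"),
            (Event("merge", 10.0, "a", "b"),),
            {"a": 50.0, "b": 50.0},
        )
        assert validate_scenario(s) == []

    def test_never_coalescing_scenario(self):
        s = Scenario(99, ("a", "b"), (), {"a": 50.0, "b": 50.0})
        assert any("no common ancestor" in v for v in validate_scenario(s))

    def test_unordered_times_detected(self):
        s = Scenario(
            99,
            ("a", "b", "c"),
            (
                Event("merge", 50.0, "a", "b"),
                Event("merge", 40.0, "b", "c"),
            ),
            {"a": 1.0, "b": 1.0, "c": 1.0},
        )
        assert any("not increasing" in v for v in validate_scenario(s))

    def test_bad_rate_detected(self):
        s = Scenario(
            99,
            ("a", "b", "c"),
            (
                Event("admix", 10.0, "a", "b", "c", 1.5),
                Event("merge", 20.0, "b", "c"),
            ),
            {"a": 1.0, "b": 1.0, "c": 1.0},
        )
        assert any("rate" in v for v in validate_scenario(s))


class TestPriors:
    def test_marginals_match_uniform_priors(self):
        """Unconstrained symbols (sizes, rates) are uniform on their
        intervals; times always satisfy the event ordering."""
        s1 = hybrid_origin_scenarios()[0]
        priors = PriorSet()
        rng = np.random.default_rng(3)
        draws = [draw_parameters(s1, priors, rng) for _ in range(3000)]
        for sym in ("N1", "N2", "Na"):
            u = (np.array([d[sym] for d in draws]) - 10) / (1e5 - 10)
            assert kstest(u, "uniform").pvalue > 1e-3
        r = np.array([d["r2"] for d in draws])
        u = (r - 0.001) / (0.999 - 0.001)
        assert kstest(u, "uniform").pvalue > 1e-3
        times = np.array([[d[t] for t in s1.time_symbols] for d in draws])
        assert (np.diff(times, axis=1) > 0).all()

    def test_bounds_lookup(self):
        priors = PriorSet()
        assert priors.bounds("N1") == (10.0, 1e5)
        assert priors.bounds("t2") == (10.0, 1e5)
        assert priors.bounds("r1") == (0.001, 0.999)
        with pytest.raises(KeyError):
            priors.bounds("x1")


class TestSimulator:
    def test_same_seed_is_bit_identical(self, scenario1):
        sizes = {p: 4 for p in hb.SAMPLED_POPULATIONS}
        a = simulate_snp_panel(
            scenario1, hb.DEFAULT_POD_PARAMS, sizes, 30, seed=5, maf_min=0.0
        )
        b = simulate_snp_panel(
            scenario1, hb.DEFAULT_POD_PARAMS, sizes, 30, seed=5, maf_min=0.0
        )
        np.testing.assert_array_equal(a.dosage, b.dosage)

    def test_panmixia_limit_fst_centred_on_zero(self):
        sc = Scenario(
            0,
            ("a", "b"),
            (Event("merge", 1e-9, "a", "b"),),
            {"a": 1000.0, "b": 1000.0},
        )
        thetas = [
            weir_cockerham_theta(p.dosage[:10], p.dosage[10:])
            for p in (
                simulate_snp_panel(sc, {}, {"a": 10, "b": 10}, 40, seed=i, maf_min=0.0)
                for i in range(150)
            )
        ]
        assert abs(float(np.mean(thetas))) < 0.01

    def test_divergence_time_increases_fst(self):
        medians = []
        for t in (50.0, 500.0, 2500.0, 10000.0):
            sc = Scenario(
                0, ("a", "b"), (Event("merge", t, "a", "b"),),
                {"a": 1000.0, "b": 1000.0},
            )
            th = [
                weir_cockerham_theta(p.dosage[:8], p.dosage[8:])
                for p in (
                    simulate_snp_panel(
                        sc, {}, {"a": 8, "b": 8}, 40, seed=1000 + i, maf_min=0.0
                    )
                    for i in range(80)
                )
            ]
            medians.append(float(np.median(th)))
        assert medians == sorted(medians)

    def test_admixture_rate_near_one_converges_to_parent_a(self, scenario1):
        """r2 -> 1 makes the hybrid's differentiation from parent A match a
        pure-divergence control, and differ strongly from parent B."""
        sizes = {p: 8 for p in hb.SAMPLED_POPULATIONS}
        params = dict(hb.DEFAULT_POD_PARAMS)
        params["r2"] = 0.999
        th_a, th_b = [], []
        for i in range(60):
            p = simulate_snp_panel(scenario1, params, sizes, 60, seed=i, maf_min=0.0)
            mic = p.dosage[np.array(p.pop_labels) == hb.MICRANTHA]
            pti = p.dosage[np.array(p.pop_labels) == hb.PTILOSPERMA]
            fla = p.dosage[np.array(p.pop_labels) == hb.FLAVIDA]
            th_a.append(weir_cockerham_theta(pti, mic))
            th_b.append(weir_cockerham_theta(pti, fla))
        assert np.median(th_a) < 0.1 < np.median(th_b)

    def test_stuck_configuration_is_labelled_error(self):
        sc = Scenario(0, ("a", "b"), (), {"a": 100.0, "b": 100.0})
        with pytest.raises(ScenarioError, match="coalesce|common ancestor"):
            simulate_snp_panel(sc, {}, {"a": 2, "b": 2}, 3, seed=1, maf_min=0.0)

    def test_allele_count_spectrum_matches_independent_simulator(self):
        """Derived-allele counts in one panmictic population follow the
        1/i-shaped spectrum of an independent coalescent simulator with the
        same one-mutation placement."""
        import msprime

        sc = Scenario(0, ("p",), (), {"p": 500.0})
        panel = simulate_snp_panel(sc, {}, {"p": 5}, 4000, seed=9, maf_min=0.0)
        mine = panel.dosage.sum(axis=0)  # 1..9 derived copies of 10
        rng = np.random.default_rng(4)
        counts_ms = []
        reps = msprime.sim_ancestry(
            samples=5, population_size=500.0, ploidy=2,
            num_replicates=4000, random_seed=77,
        )
        for ts in reps:
            tree = ts.first()
            nodes = [u for u in tree.nodes() if tree.parent(u) != -1]
            bl = np.array([tree.branch_length(u) for u in nodes])
            u = nodes[rng.choice(len(nodes), p=bl / bl.sum())]
            counts_ms.append(len(list(tree.samples(u))))
        f_mine = np.bincount(mine, minlength=10)[1:10]
        f_ms = np.bincount(counts_ms, minlength=10)[1:10]
        _stat, p, *_ = chi2_contingency(np.vstack([f_mine, f_ms]))
        assert p > 1e-3


class TestReferenceTable:
    def test_bookkeeping_and_determinism(self):
        scen = hybrid_origin_scenarios()[:2]
        sizes = {p: 4 for p in hb.SAMPLED_POPULATIONS}
        tab, meta = hb.build_reference_table(
            scen, PriorSet(), sizes, 20, 3, seed=5, maf_min=0.0
        )
        assert len(tab) == 6
        assert list(tab["scenario"]) == [1, 1, 1, 2, 2, 2]
        assert meta["n_stats"] == len(meta["stat_names"]) == 22
        assert np.isfinite(tab[meta["stat_names"]].to_numpy()).all()
        tab2, _ = hb.build_reference_table(
            scen, PriorSet(), sizes, 20, 3, seed=5, maf_min=0.0
        )
        assert tab.equals(tab2)

    def test_unused_parameters_are_nan_with_constant_schema(self):
        scen = [s for s in hybrid_origin_scenarios() if s.scenario_id in (1, 9)]
        sizes = {p: 3 for p in hb.SAMPLED_POPULATIONS}
        tab, meta = hb.build_reference_table(
            scen, PriorSet(), sizes, 10, 2, seed=8, maf_min=0.0
        )
        # scenario 9 has no admixture rates
        sc9 = tab[tab["scenario"] == 9]
        assert sc9["r1"].isna().all() and sc9["r2"].isna().all()
        sc1 = tab[tab["scenario"] == 1]
        assert sc1["r1"].notna().all()
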