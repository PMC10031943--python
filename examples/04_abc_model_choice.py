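"""ABC model choice and parameter estimation on a pseudo-observed panel.

Simulates "observed" data under the hybrid-origin scenario (admixture
fraction 0.68 from parent A), builds a small reference table for three
competing scenarios, and runs the ABC machinery: rejection on
MAD-standardized summary statistics, direct and logistic model choice,
and the local-linear logit-adjusted posterior for the admixture rate.

Note the deliberately small reference table (1000 simulations/scenario)
keeps the demo to ~1 minute; posterior sharpness grows with table size.
"""

import warnings

import pandas as pd

import hyborigin as hb
from hyborigin.abc import choose_scenario, fit_posterior

scen = {s.scenario_id: s for s in hb.hybrid_origin_scenarios()}
three = [scen[1], scen[7], scen[9]]
priors = hb.PriorSet()
sizes = {
    hb.MICRANTHA: 20, hb.PTILOSPERMA: 10, hb.NG_LINEAGE: 8, hb.FLAVIDA: 25,
}

pod, truth = hb.generate_pod(scen[1], sample_sizes=sizes, n_loci=415, seed=5)
print(f"pseudo-observed panel: truth = scenario 1, admixture r2 = {truth['r2']}")

table, meta = hb.build_reference_table(
    three, priors, sizes, n_loci=415, n_sims_per_scenario=1000,
    seed=99, maf_min=0.0,
)
names = meta["stat_names"]
obs = pd.Series(
    hb.panel_summary_stats(pod, list(hb.SAMPLED_POPULATIONS)), index=names
)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    res = choose_scenario(table, names, obs, fraction=0.05, k_direct=100)
    print("\nposterior scenario probabilities:")
    for sid in sorted(res["logistic"].probabilities):
        d = res["direct"].probabilities[sid]
        l = res["logistic"].probabilities[sid]
        print(f"  scenario {sid}: direct {d:.3f}   logistic {l:.3f}")

    bounds = {p: priors.bounds(p) for p in scen[1].parameter_names}
    post = fit_posterior(table, names, obs, 1, bounds, fraction=0.05)
r = post["r2"]
print(
    f"\nadmixture fraction from parent A: median {r.median:.3f} "
    f"(95% interval {r.q025:.3f}-{r.q975:.3f}; truth {truth['r2']})"
)
print(
    "\nScenario 1 should dominate and the r2 posterior should bracket "
    "0.68 - the same inference pattern the method produces on real "
    "hybrid data."
)
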