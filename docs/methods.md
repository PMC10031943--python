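# Methods

`hyborigin` re-implements, as a tested library, a desk pipeline for asking
whether a taxon is a homoploid hybrid between two parental species, and for
testing whether the putative hybrid occupies a drier hydraulic niche than
its parents. This note records the models, the defaults and why, the
numerical choices, and what the synthetic-data tests do and do not show.

## Genotype filtering

Input panels are diploid dosage matrices (0/1/2 copies of the alternate
allele, or missing) over anonymous unlinked SNPs, read from VCF with a
sample-to-population map. Retention rules, applied per locus in order, each
recorded in a rejection log:

1. at least one non-missing call (`all-missing` otherwise);
2. exactly two alleles;
3. missing fraction strictly below 0.20 (a locus at exactly 20% is
   dropped — "less than 20% missing" is read strictly);
4. pooled minor-allele frequency ≥ 0.05, computed over all non-missing
   calls (VCFtools `--maf` semantics);
5. Hardy–Weinberg exact test at α = 0.05, run **within** each population
   with ≥ 5 genotyped individuals; the locus is dropped when it is
   significant in more than half of the testable populations. Pooled
   testing would conflate Wahlund structure in strongly subdivided samples
   with genotyping error, which is what the HWE filter is meant to catch.

The HWE test conditions on allele counts and sums the probabilities of all
heterozygote counts no more probable than the observed one; monomorphic
loci return p = 1.

## Diversity and differentiation

Per-population summaries are averaged over loci with at least one genotyped
individual: major-allele frequency P, observed heterozygosity H_O, and
unbiased expected heterozygosity H_E = 2n/(2n−1) · 2p̂q̂. Nucleotide
diversity π is reported **per variant site** and equals H_E at a biallelic
site; per-base π is undefined for anonymous tags whose locus lengths are
out of scope, and the output metadata says so.

Differentiation is Weir & Cockerham's (1984) θ with the multi-locus
ratio-of-sums combination, and a permutation test that shuffles individuals
between the two populations; the p-value uses add-one smoothing,
p = (b+1)/(n_perm+1), so it is never exactly zero. Nei's (1972) standard
distance D = −ln(J_AB/√(J_A·J_B)) is capped at 50 when the cross-population
identity is zero, keeping ABC summary vectors finite; the cap is
unreachable for any realistic panel (it corresponds to complete fixation of
opposite alleles at every locus).

## Demographic model and simulator

A scenario is a backward-time event list over named populations with three
event kinds: `merge` (forward-time divergence), `admix` (population created
by mixing two sources; backward, each lineage picks source A with
probability r) and `pulse` (introgression: a fraction r of lineages jumps
to the source while the population persists). Sizes are diploid and
constant per population, except that an event may rebind the receiving
population's size — used to give the root its ancestral size Na. Times are
generations; coalescence within a population of size N occurs at rate
1/(2N) per lineage pair.

Each locus is an independent genealogy. Exactly one mutation is placed on
the tree with probability proportional to branch length (the fixed-S
scheme), which reproduces an ascertained SNP panel in which every locus is
variant. Loci below a minor-allele threshold are redrawn whole
(tree and mutation together), so the accepted-locus distribution is the
true conditional distribution. The default threshold is 0.05 to mirror a
MAF-filtered observed panel; the ABC stage itself uses threshold 0
(monomorphic exclusion only), matching the convention of reference-table
simulation for variant-only panels, and observed and simulated data must
always use the same setting.

The ten-scenario registry covers the hypothesis space for the two focal
lineages (putative hybrid; introgressed parental lineage): both created by
admixture (scenario 1, with the hybrid drawing a fraction r2 from parent A),
divergence-then-introgression combinations (2–6), a single hybrid origin
with later cladogenesis (7, 8), and no-hybridization nulls (9, 10).
Published descriptions of scenarios 2–10 are verbal; each encoding's
interpretation is spelled out in its `description` field rather than left
implicit. Scenario validation is structural (events on extant populations,
increasing times, rates in (0,1), a single final ancestor) and every
registry entry must pass it.

Priors are uniform: sizes and times on 10–10⁵ (diploids, generations),
admixture rates on 0.001–0.999. Time draws are rejected until they satisfy
the scenario's event ordering, i.e. the joint prior is uniform on the
ordered region; size and rate marginals remain exactly uniform. Besides t1
and t2 each scenario needs a root divergence time (and scenarios 2–4 two
more); these extra times share the same prior. Reference-table rows derive
their RNG streams from (seed, scenario, row-counter), so tables are
bit-reproducible and independent of execution order.

The simulator kernel is numba-compiled; per-population member lists give
O(1) pair sampling and a dedicated single-population loop finishes the tree
after the last event. A reference table of 3×10⁴ rows at 415 loci and 161
diploids builds in roughly 8 minutes on one core, which sets the problem
sizes used by the validation suite (below).

## ABC engine

The summary vector has 22 named entries for a four-group design: gene
diversity and proportion of monomorphic loci per group (4+4), pairwise θ
and Nei distance (6+6), and a frequency-based admixture coefficient
f = Σ(p_H−p_P2)(p_P1−p_P2) / Σ(p_P1−p_P2)² for each putatively admixed
group against the ordered parents (2). f is 1 when the hybrid matches
parent 1 and 0 when it matches parent 2; the composition is configurable
and recorded in table metadata.

Rejection standardizes each statistic by its median absolute deviation over
the reference table (robust to the heavy tails of ratio statistics),
excludes zero-MAD statistics with a warning, and keeps the ⌈fraction·n⌉
closest rows by Euclidean distance, ties broken by row order. Model choice
is reported two ways: the vote share among the k nearest rows (direct), and
multinomial logistic regression of scenario label on (stats − obs)
evaluated at the origin, with a delta-method 95% CI on each probability
from the fit's asymptotic covariance. Near-separable tables (common when
one scenario is clearly wrong) make the unpenalized likelihood diverge; the
fit then falls back to an L2-penalized multinomial regression, flagged
`penalized`, without a CI.

Parameter posteriors use local-linear regression adjustment: each accepted
draw is logit-transformed to its prior interval, regressed on
(stats − obs) with Epanechnikov weights 1−(d/d_max)², and residual-adjusted
to the observed point before back-transforming — so adjusted draws cannot
leave the prior box. Ill-conditioned designs (condition number > 1e10) get
a small ridge, flagged. Model checking projects observed and
posterior-predictive statistics into the reference table's first two
principal components (statistics standardized to zero mean, unit variance).

## Hydraulics

Water-release curves: RWC = (Wf−Wd)/(Ws−Wd); cumulative release per wood
volume CWR = (1−RWC)(Ws−Wd)(ρ·1000/Wd) in kg m⁻³ with ρ = Wd/volume.
CWR against tension x = |Ψ| is fitted with y = ax/(b+x) by multistart
nonlinear least squares (half-saturation starts 0.1–8 MPa, best RSS wins);
an all-zero release series returns a flagged degenerate fit instead of an
error. Capacitance C = ΔCWR/ΔΨ is reported for phase I (0 to b MPa,
closed form a/(2b)) and phase II (b to 8 MPa, closed form
a(8/(b+8)−½)/(8−b)); b ≥ 8 flags an empty phase II. All fitting uses
tension magnitudes; reported potentials are negative MPa.

Pressure–volume curves: the analysis plots 1/(−Ψ) against 1−RWC, where the
post-turgor relation is the straight osmotic line. The post-turgor segment
is grown from the driest point while the linear fit keeps R² ≥ 0.995 and
the next point's residual stays within a multiple of the current RMSE.
Two numerical choices matter here and are deliberate. First, the residual
guard only applies once the segment has at least 6 points (4 degrees of
freedom) — an RMSE from fewer points is unusable in either direction — and
its multiple is Studentized — max(residual_factor, t₀.₉₉₉₅ at the segment's
degrees of freedom, so ≈8.6 at 6 points shrinking toward 3 for long
segments — because an RMSE estimated from a handful of points
underestimates the noise; a fixed small multiple halts growth on a few
percent of steps under pure measurement noise, compounding into
systematically too-negative turgor-loss points, while the first pre-turgor
point overshoots even the widened tolerance by an order of magnitude (the
R² rule additionally collapses ≈0.999 → ≈0.97 at that same step). Second,
the tolerance has a small floor so that exactly collinear (noise-free)
tails do not stall on machine-epsilon RMSE. Ψ_TLP is the line's potential at the
segment's wettest point, π₀ = −1/intercept; Ψ_TLP ≤ π₀ < 0 holds by
construction. A curve that is linear throughout is returned flagged as a
boundary case (no turgid phase), not an error. With the R² threshold at
0.995, potential noise above ~3×10⁻³ MPa (on the reciprocal scale of a
leaf near −2 MPa) makes the tail fail the criterion and raises a labelled
"no linear tail" error — the method wants a careful bench-drying series.

## Synthetic data

The Balding–Nichols generator draws ancestral frequencies uniform on
(0.05, 0.95), drifts each parent with Beta(p(1−F)/F, (1−p)(1−F)/F) — the
ratio-of-sums θ between the two parents then converges to F — and samples
hybrid genotypes from the ancestry-weighted frequency w·p_A+(1−w)p_B with
w defaulting to 0.68. It is intentionally a different generative route
from the coalescent simulator, so estimator tests do not share a code path
with the simulator they help validate.

Pseudo-observed datasets default to the four-group study design — 53 / 17 /
20 / 71 diploids (the 91 parent-B samples split into the introgressed
lineage and the rest), 415 variant loci — with scenario-1 truth at the
posterior-median parameter values and r2 = 0.68. Hydraulic curve
generators invert the fitted models exactly at zero noise; the
pressure–volume generator uses Ψ_s = π₀/RWC plus a turgor term declining
linearly in RWC and vanishing at RWC_TLP (apoplastic fraction zero, bulk
modulus defaulting to the value that makes Ψ(1) = 0), so the generating
truth is Ψ_TLP = π₀/RWC_TLP.

What passing tests show — and what they do not. The synthetic panels have
no linkage, no allele-dropout or PCR-duplicate artefacts, uniform
missingness, and exactly one mutation per locus; real ddRAD panels violate
all of these to some degree. Recovery of the generating scenario and
admixture rate on synthetic data therefore validates the inference
machinery, not the biological conclusion on any real dataset, and
published statistics from the original field data (which require the raw
reads and reference-table sizes of 10⁶–10⁷) are deliberately not
reproduction targets.

## Validation problem sizes

The slow end of the test suite fixes these sizes, chosen to exercise the
full pipeline at meaningful scale: scenario recovery uses 3 maximally
distinct scenarios (1, 7, 9) × 10⁴ simulations, 415 loci, study-sized
samples, and demands the hybrid-origin scenario win logistic model choice
in ≥ 80% of 50 pseudo-observed replicates. Admixture-rate calibration
uses one scenario-1 table of 10⁴ rows at 200 loci and 15 diploids per
group, 100 prior-drawn replicates, and requires 90% posterior intervals to
cover truth 85–95% of the time. Simulator validity checks mean pairwise
TMRCA (10⁴ replicates, 3 SE), F_ST monotonicity in divergence time, and
two-sample agreement of all 22 statistics against an independent
coalescent simulator (msprime) configured with the identical demography
and mutation scheme, over 2000 panels.

## Known limitations

* Scenario topologies 2–10 are one reading of a verbal description; the
  registry is data, and alternative readings are a matter of editing event
  lists.
* The admixture coefficient f is a frequency-moment estimator; it is
  unbiased for a one-pulse hybrid but attenuates under post-hybridization
  drift in the hybrid lineage.
* Posterior sharpness at 415 loci is modest by construction — intervals
  for times and sizes are wide and strongly correlated (t/N compounds are
  what the data constrain), which matches the behaviour of this class of
  inference generally.
* The logistic model-choice CI is asymptotic; under near-separation the
  penalized fallback reports no CI rather than a fabricated one.
* Per-base π, linkage-aware statistics, read-level processing and genotype
  calling are out of scope.
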