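"""Independent brute-force oracles used to cross-check the library.

Everything here is deliberately written in the most literal way possible
(plain loops, exact rational arithmetic where feasible) and shares no code
with the package implementation.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

MISSING = -1


def hwe_exact_fraction(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE test by full enumeration with rational arithmetic.

    Conditional on allele counts, P(h heterozygotes) =
    multinomial(n; nAA, h, naa) * 2^h / C(2n, nA); the two-sided p-value
    sums configurations no more probable than the observed one.
    """
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    if n_A == 0 or n_a == 0:
        return 1.0
    denom = math.comb(2 * n, n_A)
    probs: dict[int, Fraction] = {}
    for h in range(min(n_A, n_a) % 2, min(n_A, n_a) + 1, 2):
        aa = (n_a - h) // 2
        AA = (n_A - h) // 2
        ways = (
            math.factorial(n)
            // (math.factorial(AA) * math.factorial(h) * math.factorial(aa))
        ) * 2**h
        probs[h] = Fraction(ways, denom)
    obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= obs))


def popstats_bruteforce(dosage: np.ndarray) -> dict[str, float]:
    """P, H_O, H_E (2n/(2n-1) corrected) averaged over genotyped loci."""
    n_s, n_l = dosage.shape
    P_vals, ho_vals, he_vals, n_vals = [], [], [], []
    for j in range(n_l):
        calls = [int(dosage[i, j]) for i in range(n_s) if dosage[i, j] != MISSING]
        if not calls:
            continue
        n = len(calls)
        p_alt = sum(calls) / (2 * n)
        p_major = max(p_alt, 1 - p_alt)
        ho = sum(1 for c in calls if c == 1) / n
        he = (2 * n) / (2 * n - 1) * 2 * p_alt * (1 - p_alt) if n > 0 else 0.0
        if 2 * n - 1 == 0:
            he = 0.0
        P_vals.append(p_major)
        ho_vals.append(ho)
        he_vals.append(he)
        n_vals.append(n)
    m = len(P_vals)
    return {
        "P": sum(P_vals) / m,
        "H_O": sum(ho_vals) / m,
        "H_E": sum(he_vals) / m,
        "pi": sum(he_vals) / m,
        "n_eff": sum(n_vals) / m,
    }


def wc_theta_bruteforce(groups: list[np.ndarray]) -> float:
    """Weir & Cockerham (1984) multi-locus theta for r >= 2 samples.

    Implemented from the general r-population variance-component formulas
    with explicit per-locus loops; ratio-of-sums combination.
    """
    r = len(groups)
    n_l = groups[0].shape[1]
    num = 0.0
    den = 0.0
    for j in range(n_l):
        ns, ps, hs = [], [], []
        for g in groups:
            calls = [int(g[i, j]) for i in range(g.shape[0]) if g[i, j] != MISSING]
            if not calls:
                break
            n_i = len(calls)
            ns.append(n_i)
            ps.append(sum(calls) / (2 * n_i))
            hs.append(sum(1 for c in calls if c == 1) / n_i)
        else:
            n_sum = sum(ns)
            n_bar = n_sum / r
            if n_bar <= 1:
                continue
            n_c = (n_sum - sum(n**2 for n in ns) / n_sum) / (r - 1)
            if n_c == 0:
                continue
            p_bar = sum(n * p for n, p in zip(ns, ps)) / n_sum
            s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(ns, ps)) / (
                (r - 1) * n_bar
            )
            h_bar = sum(n * h for n, h in zip(ns, hs)) / n_sum
            a = (n_bar / n_c) * (
                s2
                - (1 / (n_bar - 1))
                * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4)
            )
            b = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar)
                - ((r - 1) / r) * s2
                - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
            )
            c = h_bar / 2
            num += a
            den += a + b + c
    return num / den if den != 0 else float("nan")


def nei_bruteforce(freq_a, freq_b) -> float:
    """Nei (1972) standard distance, literal J-term computation."""
    ja = jb = jab = 0.0
    m = 0
    for pa, pb in zip(freq_a, freq_b):
        if not (math.isfinite(pa) and math.isfinite(pb)):
            continue
        ja += pa * pa + (1 - pa) * (1 - pa)
        jb += pb * pb + (1 - pb) * (1 - pb)
        jab += pa * pb + (1 - pa) * (1 - pb)
        m += 1
    ja, jb, jab = ja / m, jb / m, jab / m
    return -math.log(jab / math.sqrt(ja * jb))


def filter_bruteforce(
    dosage: np.ndarray,
    allele_labels: list[tuple[str, ...]],
    pop_of: list[str],
    maf_min: float = 0.05,
    max_missing: float = 0.20,
    hwe_alpha: float = 0.05,
    hwe_min_genotyped: int = 5,
) -> list[int]:
    """Indices of retained loci under the SNP filtering rules, re-derived
    rule by rule with plain loops."""
    n_s, n_l = dosage.shape
    pops = sorted(set(pop_of))
    keep = []
    for j in range(n_l):
        calls = [int(dosage[i, j]) for i in range(n_s) if dosage[i, j] != MISSING]
        if not calls:
            continue
        if len(allele_labels[j]) != 2:
            continue
        if (n_s - len(calls)) / n_s >= max_missing:
            continue
        p = sum(calls) / (2 * len(calls))
        if min(p, 1 - p) < maf_min:
            continue
        n_sig = n_tested = 0
        for pop in pops:
            sub = [
                int(dosage[i, j])
                for i in range(n_s)
                if pop_of[i] == pop and dosage[i, j] != MISSING
            ]
            if len(sub) < hwe_min_genotyped:
                continue
            n_tested += 1
            pval = hwe_exact_fraction(
                sum(1 for c in sub if c == 0),
                sum(1 for c in sub if c == 1),
                sum(1 for c in sub if c == 2),
            )
            if pval < hwe_alpha:
                n_sig += 1
        if n_tested > 0 and n_sig > n_tested / 2:
            continue
        keep.append(j)
    return keep


def rejection_bruteforce(
    ref: np.ndarray, obs: np.ndarray, fraction: float
) -> tuple[list[int], list[float]]:
    """Exhaustive MAD-standardized distance ranking."""
    n, m = ref.shape
    scales = []
    for j in range(m):
        col = sorted(ref[:, j])
        med = _median(col)
        scales.append(_median(sorted(abs(v - med) for v in col)))
    dists = []
    for i in range(n):
        s = 0.0
        for j in range(m):
            if scales[j] > 0:
                s += ((ref[i, j] - obs[j]) / scales[j]) ** 2
        dists.append(math.sqrt(s))
    k = math.ceil(fraction * n)
    order = sorted(range(n), key=lambda i: (dists[i], i))[:k]
    return order, [dists[i] for i in order]


def _median(sorted_vals):
    n = len(sorted_vals)
    mid = n // 2
    if n % 2:
        return sorted_vals[mid]
    return 0.5 * (sorted_vals[mid - 1] + sorted_vals[mid])


def pca_bruteforce(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of the sample covariance (descending order)."""
    C = np.cov(Z, rowvar=False, ddof=1)
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def random_genotype_matrix(rng, n_samples, n_loci, missing_rate=0.1, n_pops=2):
    """Random small dosage matrix + labels for oracle comparisons."""
    dosage = rng.integers(0, 3, size=(n_samples, n_loci)).astype(np.int8)
    mask = rng.random((n_samples, n_loci)) < missing_rate
    dosage[mask] = MISSING
    pops = [f"pop{i % n_pops}" for i in range(n_samples)]
    return dosage, pops
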