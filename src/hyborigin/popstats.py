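"""Diversity and differentiation statistics for SNP panels.

Implements the per-population diversity summaries (major-allele frequency,
observed/expected heterozygosity, nucleotide diversity at variant sites),
the Weir & Cockerham (1984) multi-locus F_ST estimator theta with a
permutation test, and Nei's (1972) standard genetic distance.

pi is reported per variant site, not per sequenced base: the loci are
anonymous ddRAD tags whose lengths are out of scope, and this convention
is recorded in the result metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeMatrix, GenotypeError

__all__ = [
    "PopStats",
    "PairwiseFst",
    "pop_stats",
    "pairwise_fst",
    "weir_cockerham_theta",
    "nei_distance",
    "NEI_DISTANCE_CAP",
]

#: Upper bound substituted for Nei's D when a shared-allele sum is zero
#: (completely non-overlapping allele pools); keeps ABC summary vectors
#: finite instead of propagating +inf.
NEI_DISTANCE_CAP: float = 50.0


@dataclass(frozen=True)
class PopStats:
    """Per-population diversity summary, averaged over genotyped loci."""

    pop: str
    P: float  # mean major-allele frequency
    H_O: float  # observed heterozygosity
    H_E: float  # unbiased expected heterozygosity, 2n/(2n-1) * 2pq
    pi: float  # nucleotide diversity per variant site
    n_eff: float  # mean genotyped individuals per locus
    n_loci: int
    metadata: dict = field(default_factory=lambda: {"pi_units": "per variant site"})


@dataclass(frozen=True)
class PairwiseFst:
    """Multi-locus Weir-Cockerham theta with a permutation p-value."""

    pop_a: str
    pop_b: str
    theta: float
    p_value: float | None
    n_perm: int
    defined: bool = True
    note: str = ""


def pop_stats(g: GenotypeMatrix, pop: str) -> PopStats:
    """Diversity statistics for one population.

    Per-locus values are averaged over loci with at least one genotyped
    individual in the population.  ``H_E`` (and ``pi``, identical at a
    biallelic site) carries the small-sample correction ``2n/(2n-1)``.
    """
    d = g.dosage[g.pop_mask(pop)]
    called = d != MISSING
    n = called.sum(axis=0).astype(float)  # diploids genotyped per locus
    usable = n > 0
    if not usable.any():
        raise GenotypeError(f"population {pop!r} has no genotyped loci")
    if (called.any(axis=1).sum()) < 2:
        raise GenotypeError(f"population {pop!r} has < 2 genotyped individuals")
    d = d[:, usable]
    called = called[:, usable]
    n = n[usable]
    alt = np.where(called, d, 0).sum(axis=0)
    p = alt / (2 * n)
    maj = np.maximum(p, 1 - p)
    h_o = np.where(called, d == 1, False).sum(axis=0) / n
    two_n = 2 * n
    h_e = np.where(two_n > 1, two_n / np.maximum(two_n - 1, 1) * 2 * p * (1 - p), 0.0)
    return PopStats(
        pop=pop,
        P=float(maj.mean()),
        H_O=float(h_o.mean()),
        H_E=float(h_e.mean()),
        pi=float(h_e.mean()),
        n_eff=float(n.mean()),
        n_loci=int(usable.sum()),
    )


def _wc_components(
    dos_a: np.ndarray, dos_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham (1984) variance components for two samples.

    Returns ``(a, a + b + c)`` arrays over loci with >= 1 genotyped diploid
    in each sample; loci failing that are dropped.
    """
    r = 2.0
    stats = []
    for dos in (dos_a, dos_b):
        called = dos != MISSING
        n_i = called.sum(axis=0).astype(float)
        alt = np.where(called, dos, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(n_i > 0, alt / np.maximum(2 * n_i, 1), np.nan)
            h_i = np.where(n_i > 0, np.where(called, dos == 1, False).sum(axis=0) / np.maximum(n_i, 1), np.nan)
        stats.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = stats
    ok = (n1 > 0) & (n2 > 0)
    n1, p1, h1, n2, p2, h2 = (x[ok] for x in (n1, p1, h1, n2, p2, h2))
    n_bar = (n1 + n2) / r
    # n_c collapses to 0 when a locus has a single diploid in each sample;
    # guard the division and let the caller drop non-finite loci.
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    with np.errstate(invalid="ignore", divide="ignore"):
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
    num = a
    den = a + b + c
    fin = np.isfinite(num) & np.isfinite(den)
    return num[fin], den[fin]


def weir_cockerham_theta(dos_a: np.ndarray, dos_b: np.ndarray) -> float:
    """Multi-locus theta as the ratio of summed variance components.

    Returns ``nan`` when no locus is polymorphic across the pair
    (denominator zero).
    """
    num, den = _wc_components(dos_a, dos_b)
    s_den = den.sum()
    if num.size == 0 or s_den == 0:
        return float("nan")
    return float(num.sum() / s_den)


def pairwise_fst(
    g: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PairwiseFst:
    """Weir-Cockerham theta between two populations with a permutation test.

    The p-value is the add-one-smoothed fraction of label permutations
    whose theta is >= the observed value: ``p = (b + 1) / (n_perm + 1)``.
    ``n_perm = 0`` skips the test (``p_value = None``).
    """
    mask_a = g.pop_mask(pop_a)
    mask_b = g.pop_mask(pop_b)
    dos_a = g.dosage[mask_a]
    dos_b = g.dosage[mask_b]
    for name, d in ((pop_a, dos_a), (pop_b, dos_b)):
        if (d != MISSING).any(axis=1).sum() < 2:
            raise GenotypeError(f"population {name!r} has < 2 genotyped individuals")
    theta = weir_cockerham_theta(dos_a, dos_b)
    if not np.isfinite(theta):
        return PairwiseFst(
            pop_a, pop_b, float("nan"), None, 0, defined=False,
            note="no polymorphic locus across the pair",
        )
    if n_perm <= 0:
        return PairwiseFst(pop_a, pop_b, theta, None, 0)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([dos_a, dos_b], axis=0)
    n_a = dos_a.shape[0]
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        t = weir_cockerham_theta(pooled[perm[:n_a]], pooled[perm[n_a:]])
        if np.isfinite(t) and t >= theta:
            exceed += 1
    return PairwiseFst(pop_a, pop_b, theta, (exceed + 1) / (n_perm + 1), n_perm)


def nei_distance(freq_a: np.ndarray, freq_b: np.ndarray) -> float:
    """Nei's (1972) standard genetic distance from biallelic frequencies.

    ``D = -ln( J_AB / sqrt(J_A * J_B) )`` with the J homozygosity/identity
    terms averaged over loci.  Loci with a missing (nan) frequency in
    either population are skipped.  If the cross-population identity J_AB
    is zero (no shared alleles anywhere) the distance is capped at
    :data:`NEI_DISTANCE_CAP` so downstream summary vectors stay finite.
    """
    pa = np.asarray(freq_a, dtype=float)
    pb = np.asarray(freq_b, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("frequency vectors must share one locus set")
    ok = np.isfinite(pa) & np.isfinite(pb)
    pa, pb = pa[ok], pb[ok]
    if pa.size == 0:
        raise ValueError("no jointly genotyped loci")
    if ((pa < 0) | (pa > 1) | (pb < 0) | (pb > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    j_a = float(np.mean(pa**2 + (1 - pa) ** 2))
    j_b = float(np.mean(pb**2 + (1 - pb) ** 2))
    j_ab = float(np.mean(pa * pb + (1 - pa) * (1 - pb)))
    if j_ab <= 0.0:
        return NEI_DISTANCE_CAP
    return float(min(NEI_DISTANCE_CAP, -np.log(j_ab / np.sqrt(j_a * j_b))))
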