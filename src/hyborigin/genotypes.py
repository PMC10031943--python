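"""Genotype matrices, VCF I/O and SNP filtering.

The central container is :class:`GenotypeMatrix`: diploid allele-dosage
calls (0/1/2 copies of the designated alternate allele, or missing) for
samples x loci, with one population label per sample.  Loci are treated as
unlinked anonymous markers; no positional arithmetic is performed.

Filtering follows the conventions of a ddRAD SNP panel destined for
population-genetic inference: biallelic sites only, a pooled minor-allele
frequency floor, a per-locus missingness ceiling, and exclusion of loci
out of Hardy-Weinberg equilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "FilterConfig",
    "GenotypeError",
    "read_popmap",
    "read_vcf",
    "write_vcf",
    "filter_snps",
    "hwe_exact_test",
    "write_rejection_log",
]

#: Sentinel dosage value for a missing diploid genotype call.
MISSING: int = -1


class GenotypeError(ValueError):
    """Raised for malformed genotype input (bad GT, unknown sample, ...)."""


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix with sample/population/locus bookkeeping.

    Parameters
    ----------
    sample_ids
        One identifier per sample (row).
    pop_labels
        One population label per sample, aligned with ``sample_ids``.
    locus_ids
        One identifier per locus (column).
    dosage
        ``(n_samples, n_loci)`` integer array with values in
        ``{0, 1, 2, MISSING}`` counting copies of the alternate allele.
    allele_labels
        Per-locus tuples ``(ref, alt, ...)``; more than two entries marks a
        multi-allelic record kept only so the filter can reject it.
    """

    sample_ids: list[str]
    pop_labels: list[str]
    locus_ids: list[str]
    dosage: np.ndarray
    allele_labels: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n_s, n_l = self.dosage.shape
        if len(self.sample_ids) != n_s:
            raise GenotypeError(
                f"{len(self.sample_ids)} sample ids for {n_s} dosage rows"
            )
        if len(self.pop_labels) != n_s:
            raise GenotypeError("every sample needs exactly one population label")
        if len(self.locus_ids) != n_l:
            raise GenotypeError(
                f"{len(self.locus_ids)} locus ids for {n_l} dosage columns"
            )
        if not self.allele_labels:
            self.allele_labels = [("A", "T")] * n_l
        if len(self.allele_labels) != n_l:
            raise GenotypeError("allele_labels length must equal locus count")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise GenotypeError(
                f"dosage contains values outside {{0,1,2,{MISSING}}} "
                f"at {int(bad.sum())} cells"
            )

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    @property
    def populations(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.pop_labels:
            seen.setdefault(p, None)
        return list(seen)

    def pop_mask(self, pop: str) -> np.ndarray:
        mask = np.array([p == pop for p in self.pop_labels])
        if not mask.any():
            raise GenotypeError(f"unknown population label {pop!r}")
        return mask

    def take_loci(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            pop_labels=list(self.pop_labels),
            locus_ids=[self.locus_ids[i] for i in idx],
            dosage=self.dosage[:, idx].copy(),
            allele_labels=[self.allele_labels[i] for i in idx],
        )

    def allele_freq(self, pop: str | None = None) -> np.ndarray:
        """Alternate-allele frequency per locus over non-missing calls.

        Loci with zero genotyped individuals (in the requested population)
        get ``nan`` rather than raising.
        """
        d = self.dosage if pop is None else self.dosage[self.pop_mask(pop)]
        called = d != MISSING
        n_alleles = 2 * called.sum(axis=0)
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)


@dataclass(frozen=True)
class FilterConfig:
    """SNP filtering thresholds.

    ``maf_min`` is applied to the pooled (all-sample) minor-allele
    frequency, matching VCFtools ``--maf`` semantics.  ``max_missing`` is
    strict: a locus is dropped when its missing fraction is >= the
    threshold ("less than 20 % missing" retained).  The HWE exact test is
    run within each population; a locus is dropped when it is significant
    in more than half of the populations with at least
    ``hwe_min_genotyped`` genotyped individuals, which keeps Wahlund
    structure from masquerading as genotyping error.
    """

    maf_min: float = 0.05
    max_missing: float = 0.20
    biallelic_only: bool = True
    hwe_alpha: float = 0.05
    hwe_min_genotyped: int = 5

    def __post_init__(self) -> None:
        for name in ("maf_min", "max_missing", "hwe_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def read_popmap(path: str) -> dict[str, str]:
    """Read a two-column (sample, population) TSV into a dict."""
    popmap: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GenotypeError(
                    f"popmap line {line_no}: expected 2 tab-separated fields"
                )
            popmap[parts[0]] = parts[1]
    return popmap


def read_vcf(path: str, popmap: dict[str, str]) -> GenotypeMatrix:
    """Read GT fields of a VCF into a :class:`GenotypeMatrix`.

    Dosage is the count of the first ALT allele; any call containing an
    allele index > 1 is kept as-is in ``allele_labels`` (so the biallelic
    filter can drop the locus) with dosage computed on allele-1 copies.
    Missing calls (``./.`` or ``.``) become :data:`MISSING`.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    missing_from_map = [s for s in samples if s not in popmap]
    if missing_from_map:
        raise GenotypeError(
            f"samples absent from popmap: {', '.join(missing_from_map)}"
        )
    locus_ids: list[str] = []
    alleles: list[tuple[str, ...]] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        lid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        gts = var.genotype.array()  # (n_samples, ploidy+1), -1 = missing
        if gts.shape[1] - 1 != 2:
            raise GenotypeError(f"locus {lid}: only diploid GTs are supported")
        a = gts[:, 0]
        b = gts[:, 1]
        dos = np.where(
            (a < 0) | (b < 0),
            MISSING,
            (a == 1).astype(np.int16) + (b == 1).astype(np.int16),
        ).astype(np.int8)
        locus_ids.append(lid)
        alleles.append(tuple([var.REF, *var.ALT]))
        rows.append(dos)
    if not rows:
        raise GenotypeError(f"no variant records in {path}")
    return GenotypeMatrix(
        sample_ids=samples,
        pop_labels=[popmap[s] for s in samples],
        locus_ids=locus_ids,
        dosage=np.stack(rows, axis=1),
        allele_labels=alleles,
    )


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=chrU>\n"
)
_GT_FOR_DOSAGE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF 4.2 (GT only) that :func:`read_vcf` round-trips."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        for j, lid in enumerate(g.locus_ids):
            ref, *alt = g.allele_labels[j]
            cols = [
                "chrU",
                str(j + 1),
                lid,
                ref,
                ",".join(alt) if alt else ".",
                ".",
                "PASS",
                ".",
                "GT",
            ]
            cols += [_GT_FOR_DOSAGE[int(d)] for d in g.dosage[:, j]]
            fh.write("\t".join(cols) + "\n")


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test for one biallelic locus.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one
    (the standard exact formulation for SNP data).

    Returns 1.0 for monomorphic input, where no deviation is testable.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_a = 2 * n_aa + n_Aa  # minor-or-not does not matter; symmetric
    n_A = 2 * n_AA + n_Aa
    if n_a == 0 or n_A == 0:
        return 1.0
    rare = min(n_a, n_A)
    # P(het = h | allele counts) ∝ n! / (nAA! nAa! naa!) * 2^h
    hets = np.arange(rare % 2, rare + 1, 2)
    logp = np.array(
        [
            h * math.log(2.0)
            - math.lgamma((rare - h) // 2 + 1)
            - math.lgamma(h + 1)
            - math.lgamma((2 * n - rare - h) // 2 + 1)
            for h in hets
        ]
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[hets == n_Aa]
    if obs.size == 0:  # impossible configuration given parity
        raise ValueError("heterozygote count inconsistent with allele counts")
    return float(min(1.0, p[p <= obs[0] * (1 + 1e-12)].sum()))


def filter_snps(
    g: GenotypeMatrix, cfg: FilterConfig | None = None
) -> tuple[GenotypeMatrix, list[tuple[str, str]]]:
    """Apply the SNP retention rules; return (filtered matrix, rejection log).

    Rules, applied in order with one recorded reason per dropped locus:

    1. ``all-missing`` — no non-missing call at the locus;
    2. ``not-biallelic`` — more than one ALT allele;
    3. ``missingness`` — missing fraction >= ``max_missing``;
    4. ``maf`` — pooled minor-allele frequency < ``maf_min``;
    5. ``hwe`` — significant HWE deviation in more than half of the
       populations with >= ``hwe_min_genotyped`` genotyped individuals.
    """
    if cfg is None:
        cfg = FilterConfig()
    if g.n_loci == 0 or g.n_samples == 0:
        raise GenotypeError("cannot filter an empty genotype matrix")

    called = g.dosage != MISSING
    n_called = called.sum(axis=0)
    miss_frac = (g.n_samples - n_called) / g.n_samples
    alt = np.where(called, g.dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(n_called > 0, alt / np.maximum(2 * n_called, 1), np.nan)
    maf = np.minimum(p_alt, 1.0 - p_alt)

    pop_masks = {p: g.pop_mask(p) for p in g.populations}

    keep = np.ones(g.n_loci, dtype=bool)
    log: list[tuple[str, str]] = []
    for j, lid in enumerate(g.locus_ids):
        if n_called[j] == 0:
            reason = "all-missing"
        elif cfg.biallelic_only and len(g.allele_labels[j]) != 2:
            reason = "not-biallelic"
        elif miss_frac[j] >= cfg.max_missing:
            reason = f"missingness={miss_frac[j]:.3f}"
        elif maf[j] < cfg.maf_min:
            reason = f"maf={maf[j]:.4f}"
        else:
            n_sig = 0
            n_tested = 0
            for mask in pop_masks.values():
                d = g.dosage[mask, j]
                d = d[d != MISSING]
                if d.size < cfg.hwe_min_genotyped:
                    continue
                n_tested += 1
                pval = hwe_exact_test(
                    int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())
                )
                if pval < cfg.hwe_alpha:
                    n_sig += 1
            if n_tested > 0 and n_sig > n_tested / 2:
                reason = f"hwe={n_sig}/{n_tested}"
            else:
                keep[j] = True
                continue
        keep[j] = False
        log.append((lid, reason))
    return g.take_loci(np.flatnonzero(keep)), log


def write_rejection_log(log: list[tuple[str, str]], path: str) -> None:
    """Write the filter rejection log as a (locus, reason) TSV."""
    with open(path, "w") as fh:
        fh.write("locus\treason\n")
        for lid, reason in log:
            fh.write(f"{lid}\t{reason}\n")
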