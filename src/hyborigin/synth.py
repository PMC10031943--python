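"""Synthetic inputs with known ground truth.

Three generators feed the pipeline end to end:

* Balding-Nichols admixed genotype panels — two parental populations
  drifted to a target F_ST around shared ancestral frequencies, plus a
  hybrid population drawing each allele from the ancestry-weighted
  parental frequency.  This is deliberately a different generative route
  from the coalescent simulator, so tests exercise both.
* Pseudo-observed datasets (PODs) — coalescent panels under a chosen
  scenario with recorded true parameters, sized like the study design
  (53 / 17 / 20 / 71 diploids, 415 variable loci) by default.
* Hydraulic curves — water-release and pressure-volume series lying
  exactly on their generating models at zero noise.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography import (
    FLAVIDA,
    MICRANTHA,
    NG_LINEAGE,
    PTILOSPERMA,
    Scenario,
    simulate_snp_panel,
)
from .genotypes import MISSING, GenotypeMatrix
from .hydraulics import PVCurve, WaterReleaseCurve

__all__ = [
    "AdmixtureSpec",
    "generate_admixed_panel",
    "DEFAULT_POD_SAMPLE_SIZES",
    "DEFAULT_POD_PARAMS",
    "generate_pod",
    "generate_water_release",
    "generate_pv",
]


@dataclass(frozen=True)
class AdmixtureSpec:
    """Design of a two-parent admixture panel.

    ``fst_parents`` is the target Weir-Cockerham differentiation between
    the parental populations; ``ancestry`` is the hybrid's genome fraction
    from parent A (the study's putative hybrid carries ~0.68 from one
    parent).
    """

    n_parental_a: int = 25
    n_parental_b: int = 25
    n_hybrid: int = 17
    n_loci: int = 500
    fst_parents: float = 0.22
    ancestry: float = 0.68
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ancestry <= 1.0:
            raise ValueError("ancestry must be in [0, 1]")
        if not 0.0 <= self.fst_parents < 1.0:
            raise ValueError("fst_parents must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if min(self.n_parental_a, self.n_parental_b, self.n_hybrid) < 1:
            raise ValueError("all sample counts must be >= 1")


def generate_admixed_panel(
    spec: AdmixtureSpec,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Balding-Nichols parental panels plus an admixed population.

    Ancestral frequencies are uniform on (0.05, 0.95); each parent's
    frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) so the between-parent
    Weir-Cockerham theta converges to ``fst_parents`` over many loci
    (F = 0 copies the ancestral frequency exactly).  Hybrid genotypes are
    Binomial(2, w p_A + (1-w) p_B); missing calls are uniform at random.

    Returns the panel and the per-hybrid-individual true ancestry
    fractions (all equal to ``spec.ancestry`` under this pooled model).
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.n_loci
    p0 = rng.uniform(0.05, 0.95, size=L)
    F = spec.fst_parents
    if F > 0:
        shape = (1.0 - F) / F
        pa = rng.beta(p0 * shape, (1 - p0) * shape)
        pb = rng.beta(p0 * shape, (1 - p0) * shape)
    else:
        pa = p0.copy()
        pb = p0.copy()
    w = spec.ancestry
    ph = w * pa + (1 - w) * pb
    blocks = []
    labels: list[str] = []
    ids: list[str] = []
    for name, n, p in (
        ("parent_a", spec.n_parental_a, pa),
        ("parent_b", spec.n_parental_b, pb),
        ("hybrid", spec.n_hybrid, ph),
    ):
        blocks.append(rng.binomial(2, p[None, :], size=(n, L)).astype(np.int8))
        labels += [name] * n
        ids += [f"{name}_{i}" for i in range(n)]
    dosage = np.concatenate(blocks, axis=0)
    if spec.missing_rate > 0:
        mask = rng.random(dosage.shape) < spec.missing_rate
        dosage[mask] = MISSING
    g = GenotypeMatrix(
        sample_ids=ids,
        pop_labels=labels,
        locus_ids=[f"L{j}" for j in range(L)],
        dosage=dosage,
    )
    return g, np.full(spec.n_hybrid, w)


#: Study-style group sizes: 53 micrantha, 17 ptilosperma, 91 flavida split
#: into the introgressed lineage (20) and the remaining populations (71).
DEFAULT_POD_SAMPLE_SIZES: dict[str, int] = {
    MICRANTHA: 53,
    PTILOSPERMA: 17,
    NG_LINEAGE: 20,
    FLAVIDA: 71,
}

#: Scenario-1 truth for pseudo-observed data: the posterior medians of the
#: four-group analysis (sizes in diploids, times in generations) with the
#: hybrid drawing ~68% of its ancestry from micrantha.
DEFAULT_POD_PARAMS: dict[str, float] = {
    "N1": 7.73e3,
    "N2": 3.30e3,
    "N3": 1.06e3,
    "N4": 1.25e4,
    "Na": 8.20e3,
    "t1": 97.9,
    "t2": 211.0,
    "t_root": 3000.0,
    "r1": 0.33,
    "r2": 0.68,
}


def generate_pod(
    scenario: Scenario,
    params: dict[str, float] | None = None,
    sample_sizes: dict[str, int] | None = None,
    n_loci: int = 415,
    seed: int = 0,
    maf_min: float = 0.0,
) -> tuple[GenotypeMatrix, dict[str, float]]:
    """Pseudo-observed dataset under a scenario with recorded truth.

    Defaults reproduce the study design: 415 variable SNPs (every locus
    ascertained variant; ``maf_min`` raises the bar to the observed-data
    filter when set to 0.05) and the four-group sample sizes.  Returns
    (panel, true parameter dict).
    """
    if params is None:
        params = {
            k: v
            for k, v in DEFAULT_POD_PARAMS.items()
            if k in scenario.parameter_names
        }
    if sample_sizes is None:
        sample_sizes = dict(DEFAULT_POD_SAMPLE_SIZES)
    panel = simulate_snp_panel(
        scenario, params, sample_sizes, n_loci, seed, maf_min=maf_min
    )
    return panel, dict(params)


def generate_water_release(
    a: float = 300.0,
    b: float = 2.0,
    noise_sd: float = 0.0,
    n_points: int = 12,
    seed: int = 0,
    psi_max: float = 8.5,
    W_d: float = 1.0,
    volume: float = 2.0,
) -> WaterReleaseCurve:
    """Water-release curve lying on CWR = a|Psi|/(b+|Psi|) plus noise.

    Tensions are spread from near 0 to beyond 8 MPa (the measurement
    protocol dries segments until Psi < -8 MPa).  The saturated mass is
    chosen so the asymptotic release at infinite tension exceeds ``a``,
    keeping all masses within [dry, saturated].  Gaussian noise with sd
    ``noise_sd`` (same units as CWR) perturbs the release values.
    """
    if a < 0 or b <= 0:
        raise ValueError("need a >= 0 and b > 0")
    rng = np.random.default_rng(seed)
    x = np.linspace(psi_max / n_points, psi_max, n_points)
    y = a * x / (b + x)
    if noise_sd > 0:
        y = np.clip(y + rng.normal(0.0, noise_sd, size=n_points), 0.0, None)
    rho = W_d / volume
    # invert CWR -> mass: CWR = (1 - RWC)(Ws - Wd) rho 1000 / Wd
    total = 1.5 * max(a, 1.0)  # releasable water at RWC=0, kg m^-3
    W_s = W_d + total * W_d / (rho * 1000.0)
    r = 1.0 - y * W_d / (rho * 1000.0 * (W_s - W_d))
    mass = W_d + r * (W_s - W_d)
    obs = np.column_stack([-x, mass])
    return WaterReleaseCurve(observations=obs, W_s=W_s, W_d=W_d, volume=volume)


def generate_pv(
    pi0: float = -1.8,
    rwc_tlp: float = 0.92,
    elasticity: float | None = None,
    noise_sd: float = 0.0,
    n_points: int = 14,
    seed: int = 0,
    rwc_min: float = 0.78,
    dry_mass: float = 0.5,
    saturated_mass: float = 1.5,
) -> tuple[PVCurve, dict[str, float]]:
    """Pressure-volume series from the two-component leaf water model.

    Osmotic potential follows the Boyle-van't Hoff relation
    ``Psi_s = pi0 / RWC`` (apoplastic fraction zero, so symplastic and
    total relative content coincide) and turgor declines linearly in RWC,
    vanishing at ``rwc_tlp``: ``Psi_p = eps (RWC - rwc_tlp)`` clipped at
    zero, with the bulk modulus ``eps`` defaulting to the value that makes
    Psi(1) = 0.  Gaussian noise with sd ``noise_sd`` (MPa) perturbs the
    potentials.  Returns the curve and the generating truth, including the
    implied Psi_TLP = pi0 / rwc_tlp.
    """
    if pi0 >= 0:
        raise ValueError("pi0 must be negative (MPa)")
    if not 0.0 < rwc_tlp < 1.0:
        raise ValueError("rwc_tlp must be in (0, 1)")
    rng = np.random.default_rng(seed)
    eps = elasticity if elasticity is not None else -pi0 / (1.0 - rwc_tlp)
    if eps <= 0:
        raise ValueError("elasticity must be positive")
    r = np.linspace(1.0, rwc_min, n_points)
    psi_s = pi0 / r
    psi_p = np.clip(eps * (r - rwc_tlp), 0.0, None)
    psi = psi_s + psi_p
    if noise_sd > 0:
        psi = psi + rng.normal(0.0, noise_sd, size=n_points)
    psi = np.minimum(psi, -1e-3)  # keep potentials physically negative
    mass = dry_mass + r * (saturated_mass - dry_mass)
    curve = PVCurve(
        observations=np.column_stack([psi, mass]),
        dry_mass=dry_mass,
        saturated_mass=saturated_mass,
    )
    truth = {
        "pi0": float(pi0),
        "rwc_tlp": float(rwc_tlp),
        "elasticity": float(eps),
        "psi_tlp": float(pi0 / rwc_tlp),
    }
    return curve, truth
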