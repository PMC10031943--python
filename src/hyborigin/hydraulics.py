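"""Plant hydraulics: water-release capacitance and pressure-volume curves.

Two analyses used to argue ecophysiological niche divergence:

* Water-release curves on woody segments: relative water content
  ``RWC = (Wf - Wd)/(Ws - Wd)``, cumulative water release per wood volume
  ``CWR = (1 - RWC) (Ws - Wd) (rho * 1000 / Wd)`` (kg m^-3), a hyperbolic
  fit ``CWR = a|Psi| / (b + |Psi|)``, and two-phase capacitance
  ``C = dCWR/dPsi`` on phases [0, b] and [b, 8] MPa of tension.

* Leaf pressure-volume curves by bench drying: the turgor-loss point
  Psi_TLP and the osmotic potential at full turgor pi0, extracted from the
  linear post-turgor tail of 1/(-Psi) against (1 - RWC).

Sign convention: fitting is done on tension x = |Psi| (MPa magnitude);
reported water potentials are negative MPa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "HydraulicsError",
    "PVCurve",
    "WaterReleaseCurve",
    "HyperbolicFit",
    "TurgorLossResult",
    "rwc",
    "cwr",
    "fit_hyperbolic",
    "capacitance",
    "turgor_loss_point",
]


class HydraulicsError(ValueError):
    """Raised for physically impossible inputs or failed fits."""


def rwc(W_f: float, W_d: float, W_s: float) -> float:
    """Relative water content (Wf - Wd) / (Ws - Wd), clipped to [0, 1].

    Values outside [0, 1] (supersaturated or "drier than dry" readings,
    both measurement artefacts) are clipped with a warning.
    """
    if W_s <= W_d:
        raise HydraulicsError(
            f"saturated mass {W_s} must exceed dry mass {W_d}"
        )
    value = (W_f - W_d) / (W_s - W_d)
    if not 0.0 <= value <= 1.0:
        warnings.warn(
            f"RWC={value:.3f} outside [0, 1]; clipping", stacklevel=2
        )
        value = float(np.clip(value, 0.0, 1.0))
    return float(value)


def cwr(rwc_value: float | np.ndarray, W_s: float, W_d: float, rho: float) -> float | np.ndarray:
    """Cumulative water release per wood volume, kg m^-3.

    ``(1 - RWC) * (Ws - Wd) * (rho * 1000 / Wd)``: zero at saturation and
    increasing as the tissue dries; at RWC = 0 it equals the total
    releasable water per unit wood volume.
    """
    if W_d <= 0:
        raise HydraulicsError("dry mass must be positive")
    if rho <= 0:
        raise HydraulicsError("wood density must be positive")
    return (1.0 - np.asarray(rwc_value, dtype=float)) * (W_s - W_d) * (rho * 1000.0 / W_d)


@dataclass
class WaterReleaseCurve:
    """Dehydration series for one woody segment.

    ``observations`` are ordered (Psi [MPa, <= 0 by convention], segment
    mass [g]) readings taken while the segment dries, ideally continuing
    until Psi falls below -8 MPa.  ``volume`` is in cm^3; wood density
    rho = Wd / volume (g cm^-3).
    """

    observations: np.ndarray  # (n, 2): water potential MPa, fresh mass g
    W_s: float
    W_d: float
    volume: float

    def __post_init__(self) -> None:
        self.observations = np.atleast_2d(np.asarray(self.observations, float))
        if self.observations.shape[1] != 2:
            raise HydraulicsError("observations must be (psi, mass) pairs")
        if self.W_s <= self.W_d:
            raise HydraulicsError("saturated mass must exceed dry mass")
        if self.W_d <= 0 or self.volume <= 0:
            raise HydraulicsError("dry mass and volume must be positive")

    @property
    def rho(self) -> float:
        return self.W_d / self.volume

    def tension_and_cwr(self) -> tuple[np.ndarray, np.ndarray]:
        """x = |Psi| and y = CWR arrays for fitting."""
        psi = self.observations[:, 0]
        mass = self.observations[:, 1]
        r = np.clip((mass - self.W_d) / (self.W_s - self.W_d), 0.0, 1.0)
        return np.abs(psi), np.asarray(cwr(r, self.W_s, self.W_d, self.rho))


@dataclass
class HyperbolicFit:
    """Fitted CWR = a x / (b + x), x = |Psi|.

    ``a`` (kg m^-3) is the asymptotic cumulative release; ``b`` (MPa) is
    the tension at half-saturation and the boundary between the rapid
    (phase I) and gradual (phase II) release phases.
    """

    a: float
    b: float
    rss: float
    degenerate: bool = False
    note: str = ""

    @property
    def phase_boundary(self) -> float:
        return self.b

    def predict(self, x: float | np.ndarray) -> float | np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a * x / (self.b + x)


def _hyperbola(x: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * x / (b + x)


def fit_hyperbolic(curve: WaterReleaseCurve) -> HyperbolicFit:
    """Nonlinear least-squares fit of the water-release hyperbola.

    Multistart over a grid of half-saturation initializations; the best
    converged start (lowest RSS) wins.  An all-zero release series is
    returned as a flagged degenerate fit (a = 0, b unidentifiable) rather
    than an error.
    """
    x, y = curve.tension_and_cwr()
    if np.unique(x).size < 4:
        raise HydraulicsError("need >= 4 observations with distinct tensions")
    if np.allclose(y, 0.0):
        return HyperbolicFit(
            a=0.0, b=float("nan"), rss=0.0, degenerate=True,
            note="no water release measured; b unidentifiable",
        )
    best: tuple[float, float, float] | None = None
    a0 = max(y.max(), 1e-6)
    for b0 in (0.1, 0.5, 1.0, 2.0, 4.0, 8.0):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _hyperbola,
                    x,
                    y,
                    p0=(a0, b0),
                    bounds=([0.0, 1e-9], [np.inf, np.inf]),
                    maxfev=20_000,
                )
        except RuntimeError:
            continue
        rss = float(np.sum((y - _hyperbola(x, *popt)) ** 2))
        if best is None or rss < best[2]:
            best = (float(popt[0]), float(popt[1]), rss)
    if best is None:
        raise HydraulicsError(
            "hyperbolic fit failed to converge from any start "
            f"(x range {x.min():.3g}-{x.max():.3g}, y max {y.max():.3g})"
        )
    return HyperbolicFit(a=best[0], b=best[1], rss=best[2])


def capacitance(
    fit: HyperbolicFit, psi_max: float = 8.0
) -> tuple[float, float | None]:
    """Two-phase capacitance C = dCWR/dPsi (kg m^-3 MPa^-1).

    Phase I spans tensions [0, b]: C_I = y(b)/b = a/(2b).  Phase II spans
    [b, psi_max]: C_II = (y(psi_max) - y(b))/(psi_max - b).  When the
    fitted b reaches psi_max the second phase is empty and C_II is None.
    """
    if fit.degenerate:
        return 0.0, None
    if fit.b <= 0 or not np.isfinite(fit.b):
        raise HydraulicsError("capacitance needs a fitted positive b")
    c1 = fit.a / (2.0 * fit.b)
    if fit.b >= psi_max:
        warnings.warn(
            f"phase boundary b={fit.b:.3g} >= psi_max={psi_max}; "
            "phase II is empty",
            stacklevel=2,
        )
        return float(c1), None
    c2 = (fit.predict(psi_max) - fit.predict(fit.b)) / (psi_max - fit.b)
    return float(c1), float(c2)


@dataclass
class PVCurve:
    """Leaf pressure-volume observations from bench drying.

    ``observations`` are ordered (Psi [MPa, <= 0], fresh mass [g]) pairs;
    Psi is not assumed monotone (measurement noise).  ``leaf_area`` (m^2)
    is kept for per-area reporting only; the turgor-loss math uses masses.
    """

    observations: np.ndarray
    dry_mass: float
    saturated_mass: float
    leaf_area: float | None = None

    def __post_init__(self) -> None:
        self.observations = np.atleast_2d(np.asarray(self.observations, float))
        if self.observations.shape[1] != 2:
            raise HydraulicsError("observations must be (psi, mass) pairs")
        if self.saturated_mass <= self.dry_mass:
            raise HydraulicsError("saturated mass must exceed dry mass")
        if (self.observations[:, 0] > 0).any():
            raise HydraulicsError("water potentials must be <= 0 MPa")


@dataclass
class TurgorLossResult:
    """Turgor-loss point extracted from a P-V curve."""

    psi_tlp: float  # MPa, negative
    pi_0: float  # osmotic potential at full turgor, MPa, negative
    rwc_tlp: float  # relative water content at turgor loss
    slope: float  # post-turgor line slope in (1/-Psi) vs (1-RWC)
    intercept: float
    n_linear: int  # points in the post-turgor segment
    r_squared: float
    boundary: bool = False  # True when the whole curve was post-turgor
    note: str = ""


def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Least-squares line; returns (slope, intercept, r^2, rmse)."""
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    rmse = float(np.sqrt(ss_res / max(1, x.size - 2)))
    return float(coef[0]), float(coef[1]), r2, rmse


def turgor_loss_point(
    pv: PVCurve,
    min_points: int = 3,
    r2_min: float = 0.995,
    residual_factor: float = 3.0,
) -> TurgorLossResult:
    """Extract Psi_TLP and pi0 from a pressure-volume curve.

    Standard P-V analysis: plot 1/(-Psi) against x = 1 - RWC; beyond
    turgor loss the relation is the straight osmotic line.  The segment is
    grown from the driest point toward hydration while the linear fit
    keeps R^2 >= ``r2_min`` and the candidate point's residual stays
    within ``residual_factor`` times the current RMSE.  Psi_TLP is the
    potential of the line at the segment's wettest point; pi0 = -1 /
    intercept.  A curve that is linear throughout (no turgor anywhere) is
    returned flagged as a boundary case with Psi_TLP at the first
    (wettest) observation.
    """
    psi = pv.observations[:, 0]
    mass = pv.observations[:, 1]
    if np.unique(psi).size < 6:
        raise HydraulicsError("need >= 6 distinct observations spanning the TLP")
    if (psi >= 0).all():
        raise HydraulicsError("all potentials are zero; leaf never dried")
    r = np.clip(
        (mass - pv.dry_mass) / (pv.saturated_mass - pv.dry_mass), 0.0, 1.0
    )
    x = 1.0 - r
    with np.errstate(divide="ignore"):
        y = 1.0 / (-psi)
    ok = np.isfinite(y)
    x, y, psi = x[ok], y[ok], psi[ok]
    order = np.argsort(x)  # wettest -> driest
    x, y, psi = x[order], y[order], psi[order]
    n = x.size
    if n < min_points + 1:
        raise HydraulicsError("too few finite observations for the P-V fit")
    # grow the post-turgor segment from the dry end
    seg = min_points
    slope, icept, r2, rmse = _linfit(x[n - seg :], y[n - seg :])
    if r2 < r2_min:
        raise HydraulicsError(
            f"no linear post-turgor tail: R^2={r2:.4f} on the driest "
            f"{seg} points"
        )
    from scipy.stats import t as t_dist

    y_scale = float(np.ptp(y[n - seg :])) + abs(float(y[n - 1]))
    while seg < n:
        cand = n - seg - 1
        pred = slope * x[cand] + icept
        # Studentize the residual threshold: an RMSE from few points
        # underestimates the noise, so the factor widens at low degrees of
        # freedom (per-step false-stop rate ~0.1%) while the first
        # pre-turgor point still overshoots it by an order of magnitude.
        # The additive floor keeps exactly collinear (noise-free) tails
        # growing instead of stalling on rmse ~ machine epsilon.
        factor = max(residual_factor, float(t_dist.ppf(0.9995, max(1, seg - 2))))
        tol = factor * rmse + 1e-7 * y_scale + 1e-12
        # below 6 points the RMSE can be freakishly small as well as large;
        # rely on the R^2 rule alone until the estimate has >= 4 dof
        if seg >= 6 and abs(y[cand] - pred) > tol:
            break
        s2, i2, r2_new, rmse2 = _linfit(x[cand:], y[cand:])
        if r2_new < r2_min:
            break
        seg += 1
        slope, icept, r2, rmse = s2, i2, r2_new, rmse2
    first = n - seg  # wettest point of the post-turgor segment
    y_tlp = slope * x[first] + icept
    if y_tlp <= 0 or icept <= 0:
        raise HydraulicsError(
            "post-turgor line extrapolates to non-negative potential; "
            "curve does not support a turgor-loss point"
        )
    boundary = seg >= n
    return TurgorLossResult(
        psi_tlp=float(-1.0 / y_tlp),
        pi_0=float(-1.0 / icept),
        rwc_tlp=float(1.0 - x[first]),
        slope=slope,
        intercept=icept,
        n_linear=int(seg),
        r_squared=float(r2),
        boundary=boundary,
        note="entire curve post-turgor (no turgid phase detected)"
        if boundary
        else "",
    )
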