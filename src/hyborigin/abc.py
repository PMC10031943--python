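"""Approximate Bayesian computation: summary statistics, rejection,
model choice and local-linear posterior adjustment.

The workflow mirrors standard SNP-panel ABC practice: a named summary
vector (per-group gene diversity, monomorphism proportions, pairwise
Weir-Cockerham F_ST, pairwise Nei distance, and frequency-based admixture
coefficients f for each putatively admixed group), distances standardized
by each statistic's median absolute deviation over the reference table,
model choice by nearest-neighbour vote share (direct) and multinomial
logistic regression evaluated at the observed point, and parameter
posteriors by Epanechnikov-weighted local-linear regression on a logit
scale so adjusted draws stay inside their prior bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .popstats import NEI_DISTANCE_CAP

__all__ = [
    "default_admixed_specs",
    "stat_names",
    "panel_summary_stats",
    "summary_stats",
    "RejectionResult",
    "rejection_select",
    "ModelChoiceResult",
    "model_choice_direct",
    "model_choice_logistic",
    "ParamPosterior",
    "estimate_posterior",
    "model_check_pca",
    "choose_scenario",
    "fit_posterior",
]


def default_admixed_specs(
    sample_sizes: dict[str, int] | None = None,
) -> list[tuple[str, str, str]]:
    """Admixture statistics for (hybrid; parent1, parent2) triples.

    The default mirrors the four-group hybrid-origin design: both focal
    lineages tested against the two parental species, with micrantha as
    ordered parent 1 so f is the micrantha-ancestry coefficient.
    """
    from .demography import FLAVIDA, MICRANTHA, NG_LINEAGE, PTILOSPERMA

    specs = [
        (PTILOSPERMA, MICRANTHA, FLAVIDA),
        (NG_LINEAGE, MICRANTHA, FLAVIDA),
    ]
    if sample_sizes is not None:
        specs = [
            s
            for s in specs
            if all(sample_sizes.get(p, 0) > 0 for p in s)
        ]
    return specs


def stat_names(
    groups: Sequence[str], admixed_specs: Sequence[tuple[str, str, str]]
) -> list[str]:
    """Column names of the summary-statistic vector, in canonical order."""
    names = [f"gene_div_{g}" for g in groups]
    names += [f"prop_mono_{g}" for g in groups]
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            names.append(f"fst_{a}_{b}")
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            names.append(f"nei_{a}_{b}")
    for h, p1, p2 in admixed_specs:
        names.append(f"admix_f_{h}_{p1}_{p2}")
    return names


def _group_freq_het(
    dosage: np.ndarray, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(freq, obs-het, n-called) per locus for one group; nan where empty."""
    d = dosage[idx]
    called = d != MISSING
    n = called.sum(axis=0).astype(float)
    alt = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)
        h = np.where(n > 0, np.where(called, d == 1, False).sum(axis=0) / np.maximum(n, 1), np.nan)
    return p, h, n


def _pair_theta(
    p1: np.ndarray, h1: np.ndarray, n1: np.ndarray,
    p2: np.ndarray, h2: np.ndarray, n2: np.ndarray,
) -> float:
    """Multi-locus Weir-Cockerham theta from per-group per-locus moments."""
    r = 2.0
    ok = (n1 > 0) & (n2 > 0)
    if not ok.any():
        return 0.0
    n1, p1, h1, n2, p2, h2 = (x[ok] for x in (n1, p1, h1, n2, p2, h2))
    n_bar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - ((r - 1) / r) * s2
            - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
    c = h_bar / 2
    num, den = a, a + b + c
    fin = np.isfinite(num) & np.isfinite(den)
    s_den = den[fin].sum()
    if s_den == 0:
        return 0.0
    return float(num[fin].sum() / s_den)


def _nei(pa: np.ndarray, pb: np.ndarray) -> float:
    ok = np.isfinite(pa) & np.isfinite(pb)
    pa, pb = pa[ok], pb[ok]
    if pa.size == 0:
        return 0.0
    j_a = np.mean(pa**2 + (1 - pa) ** 2)
    j_b = np.mean(pb**2 + (1 - pb) ** 2)
    j_ab = np.mean(pa * pb + (1 - pa) * (1 - pb))
    if j_ab <= 0:
        return NEI_DISTANCE_CAP
    return float(min(NEI_DISTANCE_CAP, -np.log(j_ab / np.sqrt(j_a * j_b))))


def _admix_f(ph: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Frequency-based admixture coefficient of the hybrid toward parent 1.

    f = sum((p_H - p_P2)(p_P1 - p_P2)) / sum((p_P1 - p_P2)^2): 1 when the
    hybrid matches parent 1, 0 when it matches parent 2.  Returns 0.5
    (uninformative) when the parents are identical at every locus.
    """
    ok = np.isfinite(ph) & np.isfinite(p1) & np.isfinite(p2)
    ph, p1, p2 = ph[ok], p1[ok], p2[ok]
    den = float(np.sum((p1 - p2) ** 2))
    if den == 0.0:
        return 0.5
    return float(np.sum((ph - p2) * (p1 - p2)) / den)


def panel_summary_stats(
    g: GenotypeMatrix,
    groups: Sequence[str] | None = None,
    admixed_specs: Sequence[tuple[str, str, str]] | None = None,
) -> np.ndarray:
    """Summary-statistic vector for one panel (see :func:`stat_names`).

    Deterministic, finite, and identically ordered for observed and
    simulated data.  Gene diversity carries the 2n/(2n-1) small-sample
    correction; monomorphism is judged on the group's called genotypes.
    """
    if groups is None:
        groups = g.populations
    if len(groups) < 2:
        raise ValueError("need at least two groups for summary statistics")
    for grp in groups:
        g.pop_mask(grp)  # raises GenotypeError for unknown labels
    if admixed_specs is None:
        admixed_specs = [
            s for s in default_admixed_specs() if all(p in groups for p in s)
        ]
    idx = {grp: np.flatnonzero(g.pop_mask(grp)) for grp in groups}
    moments = {grp: _group_freq_het(g.dosage, idx[grp]) for grp in groups}
    out: list[float] = []
    for grp in groups:  # gene diversity
        p, _h, n = moments[grp]
        ok = n > 0
        two_n = 2 * n[ok]
        hexp = two_n / np.maximum(two_n - 1, 1) * 2 * p[ok] * (1 - p[ok])
        out.append(float(hexp.mean()) if ok.any() else 0.0)
    for grp in groups:  # proportion of monomorphic loci
        p, _h, n = moments[grp]
        mono = (n == 0) | (p <= 0) | (p >= 1)
        out.append(float(mono.mean()))
    pairs = [
        (a, b) for i, a in enumerate(groups) for b in list(groups)[i + 1 :]
    ]
    for a, b in pairs:  # pairwise Weir-Cockerham theta
        pa, ha, na = moments[a]
        pb, hb, nb = moments[b]
        out.append(_pair_theta(pa, ha, na, pb, hb, nb))
    for a, b in pairs:  # pairwise Nei distance
        out.append(_nei(moments[a][0], moments[b][0]))
    for h, p1, p2 in admixed_specs:
        out.append(_admix_f(moments[h][0], moments[p1][0], moments[p2][0]))
    vec = np.array(out, dtype=float)
    vec[~np.isfinite(vec)] = 0.0
    return vec


def summary_stats(
    g: GenotypeMatrix,
    group_map: dict[str, str] | None = None,
    admixed_specs: Sequence[tuple[str, str, str]] | None = None,
) -> pd.Series:
    """Named summary-statistic vector for an observed panel.

    ``group_map`` optionally maps each population label to a coarser group
    (e.g. many field populations onto the four analysis groups).
    """
    if group_map is not None:
        labels = [group_map.get(p, p) for p in g.pop_labels]
        g = GenotypeMatrix(
            sample_ids=list(g.sample_ids),
            pop_labels=labels,
            locus_ids=list(g.locus_ids),
            dosage=g.dosage.copy(),
            allele_labels=list(g.allele_labels),
        )
    groups = g.populations
    if admixed_specs is None:
        admixed_specs = [
            s for s in default_admixed_specs() if all(p in groups for p in s)
        ]
    vals = panel_summary_stats(g, groups, admixed_specs)
    return pd.Series(vals, index=stat_names(groups, admixed_specs))


@dataclass
class RejectionResult:
    """Rows accepted by the rejection step, nearest first."""

    indices: np.ndarray  # positions into the reference table, sorted by distance
    distances: np.ndarray  # matching distances, ascending
    used_stats: list[str]  # statistics that entered the distance
    scale: np.ndarray  # MAD scale per used statistic
    dropped_stats: list[str] = field(default_factory=list)


def _mad(x: np.ndarray) -> np.ndarray:
    med = np.median(x, axis=0)
    return np.median(np.abs(x - med), axis=0)


def rejection_select(
    ref_stats: pd.DataFrame | np.ndarray,
    obs: pd.Series | np.ndarray,
    fraction: float,
) -> RejectionResult:
    """Select the closest ``ceil(fraction * n)`` simulations.

    Distances are Euclidean on statistics standardized by the reference
    table's per-statistic median absolute deviation; zero-MAD statistics
    are excluded with a warning.  Ties are broken by row order.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if isinstance(ref_stats, pd.DataFrame):
        names = list(ref_stats.columns)
        X = ref_stats.to_numpy(dtype=float)
    else:
        X = np.asarray(ref_stats, dtype=float)
        names = [f"s{i}" for i in range(X.shape[1])]
    y = (
        obs.reindex(names).to_numpy(dtype=float)
        if isinstance(obs, pd.Series)
        else np.asarray(obs, dtype=float)
    )
    if y.shape[0] != X.shape[1]:
        raise ValueError("observed vector length != number of statistics")
    scale = _mad(X)
    usable = scale > 0
    if not usable.all():
        dropped = [n for n, u in zip(names, usable) if not u]
        warnings.warn(
            f"excluding zero-variance statistics from distance: {dropped}",
            stacklevel=2,
        )
    else:
        dropped = []
    if not usable.any():
        raise ValueError("all statistics have zero spread in the reference table")
    d = np.sqrt(
        (((X[:, usable] - y[usable]) / scale[usable]) ** 2).sum(axis=1)
    )
    n_keep = int(np.ceil(fraction * X.shape[0]))
    order = np.argsort(d, kind="stable")[:n_keep]
    return RejectionResult(
        indices=order,
        distances=d[order],
        used_stats=[n for n, u in zip(names, usable) if u],
        scale=scale[usable],
        dropped_stats=dropped,
    )


@dataclass
class ModelChoiceResult:
    """Per-scenario posterior probabilities (direct and/or logistic)."""

    probabilities: dict[int, float]
    method: str
    ci: dict[int, tuple[float, float]] | None = None
    penalized: bool = False

    @property
    def best(self) -> int:
        return max(self.probabilities, key=self.probabilities.get)


def model_choice_direct(
    scenario_labels: np.ndarray, k: int, scenarios: Sequence[int] | None = None
) -> ModelChoiceResult:
    """Vote shares of each scenario among the k nearest accepted rows.

    ``scenario_labels`` must be ordered nearest-first (as returned through
    :class:`RejectionResult.indices`).
    """
    labels = np.asarray(scenario_labels)
    if k > labels.shape[0]:
        raise ValueError(f"k={k} exceeds the {labels.shape[0]} accepted rows")
    top = labels[:k]
    if scenarios is None:
        scenarios = sorted(set(labels.tolist()))
    probs = {int(s): float((top == s).sum() / k) for s in scenarios}
    return ModelChoiceResult(probabilities=probs, method="direct")


def model_choice_logistic(
    selected_stats: np.ndarray,
    selected_labels: np.ndarray,
    obs: np.ndarray,
    scale: np.ndarray | None = None,
) -> ModelChoiceResult:
    """Multinomial logistic regression of scenario label on (stats - obs).

    Probabilities are the fitted class probabilities at the observed point
    (the regression origin); 95% CIs come from the delta method on the
    fit's asymptotic covariance.  On separation/convergence failure the
    fit falls back to an L2-penalized multinomial regression (flagged,
    no CI).
    """
    import statsmodels.api as sm

    labels = np.asarray(selected_labels)
    classes = np.array(sorted(set(labels.tolist())))
    if classes.size < 2:
        raise ValueError("need >= 2 scenarios among selected rows")
    X = np.asarray(selected_stats, dtype=float) - np.asarray(obs, dtype=float)
    if scale is not None:
        X = X / scale
    y = np.searchsorted(classes, labels)
    exog = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MNLogit(y, exog).fit(disp=0, maxiter=200)
        if not np.isfinite(res.params.to_numpy() if hasattr(res.params, "to_numpy") else res.params).all():
            raise np.linalg.LinAlgError("non-finite MNLogit parameters")
        params = np.asarray(res.params)  # (k_exog, n_classes-1)
        eta = np.concatenate([[0.0], params[0, :]])  # intercepts at x=0
        e = np.exp(eta - eta.max())
        p = e / e.sum()
        cov = np.asarray(res.cov_params())
        k_exog = exog.shape[1]
        n_alt = classes.size - 1
        # params are raveled per equation: intercept of eq j at j*k_exog
        icept_idx = [j * k_exog for j in range(n_alt)]
        V = cov[np.ix_(icept_idx, icept_idx)]
        ci: dict[int, tuple[float, float]] = {}
        for j, cls in enumerate(classes):
            grad = np.array(
                [p[j] * ((1.0 if j == m + 1 else 0.0) - p[m + 1]) for m in range(n_alt)]
            )
            se = float(np.sqrt(max(0.0, grad @ V @ grad)))
            ci[int(cls)] = (
                float(max(0.0, p[j] - 1.96 * se)),
                float(min(1.0, p[j] + 1.96 * se)),
            )
        probs = {int(c): float(p[j]) for j, c in enumerate(classes)}
        return ModelChoiceResult(probs, method="logistic", ci=ci)
    except (np.linalg.LinAlgError, ValueError, RuntimeError):
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=100.0, max_iter=5000)
        clf.fit(X, y)
        p = clf.predict_proba(np.zeros((1, X.shape[1])))[0]
        probs = {int(c): float(p[j]) for j, c in enumerate(classes)}
        return ModelChoiceResult(
            probs, method="logistic", ci=None, penalized=True
        )


@dataclass
class ParamPosterior:
    """Adjusted posterior for one parameter."""

    name: str
    sample: np.ndarray
    median: float
    q025: float
    q975: float
    ridged: bool = False

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.sample, q))

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        return self.quantile(a), self.quantile(1.0 - a)


def _logit(u: np.ndarray) -> np.ndarray:
    return np.log(u) - np.log1p(-u)


def estimate_posterior(
    selected_params: pd.DataFrame,
    selected_stats: np.ndarray,
    distances: np.ndarray,
    obs: np.ndarray,
    priors: dict[str, tuple[float, float]],
    scale: np.ndarray | None = None,
) -> dict[str, ParamPosterior]:
    """Local-linear regression adjustment of accepted parameter draws.

    Each parameter is logit-transformed to its prior interval, regressed
    on (stats - obs) with Epanechnikov weights ``1 - (d/d_max)^2``, and
    residual-adjusted to the observed point before back-transforming, so
    every adjusted draw remains inside the prior bounds.  A singular
    design triggers a small ridge penalty (flagged).
    """
    if len(selected_params) < 20:
        raise ValueError("need >= 20 accepted rows for the local regression")
    X = np.asarray(selected_stats, dtype=float) - np.asarray(obs, dtype=float)
    if scale is not None:
        X = X / scale
    d = np.asarray(distances, dtype=float)
    dmax = d.max()
    w = 1.0 - (d / dmax) ** 2 if dmax > 0 else np.ones_like(d)
    w = np.maximum(w, 1e-12)
    design = np.column_stack([np.ones(len(X)), X])
    WD = design * w[:, None]
    A = design.T @ WD
    out: dict[str, ParamPosterior] = {}
    eps = 1e-9
    for name in selected_params.columns:
        theta = selected_params[name].to_numpy(dtype=float)
        if name not in priors:
            raise KeyError(f"no prior bounds for parameter {name!r}")
        lo, hi = priors[name]
        if not np.all((theta >= lo) & (theta <= hi)):
            raise ValueError(f"accepted draws for {name!r} outside prior bounds")
        u = np.clip((theta - lo) / (hi - lo), eps, 1 - eps)
        z = _logit(u)
        rhs = design.T @ (w * z)
        ridged = False
        try:
            cond = np.linalg.cond(A)
            if not np.isfinite(cond) or cond > 1e10:
                raise np.linalg.LinAlgError
            beta = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            ridged = True
            lam = 1e-6 * np.trace(A) / A.shape[0]
            beta = np.linalg.solve(A + lam * np.eye(A.shape[0]), rhs)
        z_adj = z - X @ beta[1:]
        theta_adj = lo + (hi - lo) / (1.0 + np.exp(-z_adj))
        out[name] = ParamPosterior(
            name=name,
            sample=theta_adj,
            median=float(np.median(theta_adj)),
            q025=float(np.quantile(theta_adj, 0.025)),
            q975=float(np.quantile(theta_adj, 0.975)),
            ridged=ridged,
        )
    return out


def model_check_pca(
    ref_stats: pd.DataFrame | np.ndarray,
    posterior_stats: pd.DataFrame | np.ndarray | None,
    obs: pd.Series | np.ndarray,
    n_components: int = 2,
) -> dict[str, np.ndarray]:
    """Project reference, posterior-predictive and observed statistics into
    the reference table's principal-component plane.

    The PCA is fitted on the reference statistics standardized to zero
    mean and unit variance (zero-variance columns dropped); returns
    coordinate arrays plus the explained variances.
    """
    from sklearn.decomposition import PCA

    X = (
        ref_stats.to_numpy(dtype=float)
        if isinstance(ref_stats, pd.DataFrame)
        else np.asarray(ref_stats, dtype=float)
    )
    y = (
        obs.to_numpy(dtype=float)
        if isinstance(obs, pd.Series)
        else np.asarray(obs, dtype=float)
    )
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    pca = PCA(n_components=min(n_components, Z.shape[1]))
    ref_xy = pca.fit_transform(Z)
    obs_xy = pca.transform(((y[keep] - mu[keep]) / sd[keep])[None, :])[0]
    out = {
        "reference": ref_xy,
        "observed": obs_xy,
        "explained_variance": pca.explained_variance_,
        "components": pca.components_,
    }
    if posterior_stats is not None:
        P = (
            posterior_stats.to_numpy(dtype=float)
            if isinstance(posterior_stats, pd.DataFrame)
            else np.asarray(posterior_stats, dtype=float)
        )
        out["posterior"] = pca.transform((P[:, keep] - mu[keep]) / sd[keep])
    return out


def choose_scenario(
    table: pd.DataFrame,
    stat_names_: Sequence[str],
    obs: pd.Series | np.ndarray,
    fraction: float = 0.01,
    k_direct: int = 500,
) -> dict:
    """Rejection step plus both model-choice routes on a reference table.

    ``table`` must carry a ``scenario`` column and the named statistic
    columns.  Returns the rejection result and the direct / logistic
    :class:`ModelChoiceResult` objects.
    """
    names = list(stat_names_)
    sel = rejection_select(table[names], obs, fraction)
    labels = table["scenario"].to_numpy()[sel.indices]
    obs_vec = (
        obs.reindex(names).to_numpy(dtype=float)
        if isinstance(obs, pd.Series)
        else np.asarray(obs, dtype=float)
    )
    used_idx = [names.index(n) for n in sel.used_stats]
    stats_sel = table[sel.used_stats].to_numpy()[sel.indices]
    direct = model_choice_direct(
        labels, min(k_direct, len(labels)),
        scenarios=sorted(set(table["scenario"].tolist())),
    )
    logistic = model_choice_logistic(
        stats_sel, labels, obs_vec[used_idx], scale=sel.scale
    )
    return {"selection": sel, "direct": direct, "logistic": logistic}


def fit_posterior(
    table: pd.DataFrame,
    stat_names_: Sequence[str],
    obs: pd.Series | np.ndarray,
    scenario_id: int,
    priors: dict[str, tuple[float, float]],
    fraction: float = 0.01,
) -> dict[str, ParamPosterior]:
    """Parameter posterior for one scenario's rows of a reference table.

    Re-runs the rejection step within the scenario's rows (mirroring the
    practice of estimating parameters under the chosen model only) and
    applies the local-linear logit adjustment for every parameter the
    scenario uses (the keys of ``priors``).
    """
    names = list(stat_names_)
    sub = table[table["scenario"] == scenario_id].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no rows for scenario {scenario_id}")
    sel = rejection_select(sub[names], obs, fraction)
    obs_vec = (
        obs.reindex(names).to_numpy(dtype=float)
        if isinstance(obs, pd.Series)
        else np.asarray(obs, dtype=float)
    )
    used_idx = [names.index(n) for n in sel.used_stats]
    stats_sel = sub[sel.used_stats].to_numpy()[sel.indices]
    params = sub[list(priors)].iloc[sel.indices]
    return estimate_posterior(
        params, stats_sel, sel.distances, obs_vec[used_idx], priors,
        scale=sel.scale,
    )
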