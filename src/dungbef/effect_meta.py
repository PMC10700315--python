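"""Paired effect sizes and spatially-correlated random-effects meta-analysis.

Each landscape contributes one Hedges' *g*: the bias-corrected
standardized mean difference in dung removal rate between its low- and
high-intensity pastures (positive g = more removal under low intensity).
The g values are then pooled with a random-effects model

    g_i = X_i beta + u_i + e_i,   u ~ N(0, T^2 R(rho)),   e_i ~ N(0, v_i)

where ``v_i`` is the known sampling variance of g_i and ``R`` is one of
five between-site correlation structures (independent, exponential,
Gaussian, rational quadratic, spherical) over great-circle distances.
(T^2, rho) are estimated by restricted maximum likelihood, beta by
generalized least squares at the optimum; structures are compared by
small-sample AICc.  Moderators (climate, cattle-density differences,
diversity differences) enter through the design matrix; coefficient tests
use t references with n - m - 1 degrees of freedom and the moderators are
tested jointly with an F-test, matching small-sample meta-regression
practice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "STRUCTURES",
    "EffectSize",
    "MetaFit",
    "MetaRegressionFit",
    "ConvergenceError",
    "hedges_g",
    "effect_sizes",
    "great_circle_distance",
    "distance_matrix_km",
    "spatial_correlation",
    "random_effects_fit",
    "select_structure",
    "meta_regression",
    "heterogeneity",
    "paired_wilcoxon",
]

STRUCTURES = ("none", "exponential", "gaussian", "rational_quadratic", "spherical")

EARTH_RADIUS_KM = 6371.0

#: Condition-number threshold above which moderators are declared collinear.
COLLINEARITY_THRESHOLD = 1e6


class ConvergenceError(RuntimeError):
    """REML optimization failed; carries the optimizer trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class EffectSize:
    """One landscape's standardized mean difference in removal rate."""

    site_id: str
    g: float
    var_g: float
    n_low: int
    n_high: int
    latitude: float = math.nan
    longitude: float = math.nan


@dataclass
class MetaFit:
    """Fitted random-effects model (intercept only)."""

    mu: float
    se_mu: float
    t: float
    df: int
    p: float
    ci_low: float
    ci_high: float
    tau2: float
    Q: float
    Q_df: int
    Q_p: float
    I2: float
    structure: str
    rho: float | None
    rll: float
    aicc: float
    n: int
    k_params: int


@dataclass
class MetaRegressionFit:
    """Fitted random-effects meta-regression."""

    table: pd.DataFrame        # per-term estimate, se, t, df, p, vif
    F: float
    F_df: tuple[int, int]
    F_p: float
    pseudo_R2: float
    tau2: float
    tau2_intercept_only: float
    structure: str
    rho: float | None
    rll: float
    aicc: float
    n: int
    moderators: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------------

def hedges_g(low, high, site_id: str = "", latitude: float = math.nan,
             longitude: float = math.nan) -> EffectSize:
    """Hedges' g between two replicate groups (low minus high).

    d = (mean_low - mean_high) / s_pooled with (n-1)-weighted pooled SD;
    the small-sample correction is J = 1 - 3 / (4(n1 + n2 - 2) - 1) and
    var(g) = J^2 [ (n1 + n2)/(n1 n2) + d^2 / (2(n1 + n2 - 2)) ].
    """
    low = np.asarray(low, dtype=float)
    high = np.asarray(high, dtype=float)
    n1, n2 = len(low), len(high)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two replicates")
    if not (np.isfinite(low).all() and np.isfinite(high).all()):
        raise ValueError("replicate values must be finite")
    diff = low.mean() - high.mean()
    s2p = ((n1 - 1) * low.var(ddof=1) + (n2 - 1) * high.var(ddof=1)) / (n1 + n2 - 2)
    if s2p == 0:
        if diff != 0:
            raise ValueError("zero pooled SD with unequal means: g is undefined")
        d = 0.0
    else:
        d = diff / math.sqrt(s2p)
    J = 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0)
    g = J * d
    var_g = J ** 2 * ((n1 + n2) / (n1 * n2) + d ** 2 / (2.0 * (n1 + n2 - 2)))
    return EffectSize(site_id=site_id, g=g, var_g=var_g, n_low=n1, n_high=n2,
                      latitude=latitude, longitude=longitude)


def effect_sizes(removal_units: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Per-landscape Hedges' g from the unit-level removal table.

    Coordinates are the landscape centroid (mean of its two pastures).
    Returns a DataFrame with ``landscape_id``, ``g``, ``var_g``, ``n_low``,
    ``n_high``, ``latitude``, ``longitude``.
    """
    merged = removal_units.merge(sites[["site_id", "landscape_id"]], on="site_id")
    rows = []
    for landscape_id, grp in merged.groupby("landscape_id", sort=True):
        low = grp.loc[grp["regime"] == "low", "drr"].to_numpy()
        high = grp.loc[grp["regime"] == "high", "drr"].to_numpy()
        coords = sites[sites["landscape_id"] == landscape_id]
        es = hedges_g(low, high, site_id=str(landscape_id),
                      latitude=float(coords["latitude"].mean()),
                      longitude=float(coords["longitude"].mean()))
        rows.append({"landscape_id": landscape_id, "g": es.g, "var_g": es.var_g,
                     "n_low": es.n_low, "n_high": es.n_high,
                     "latitude": es.latitude, "longitude": es.longitude})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Distances and correlation structures
# ---------------------------------------------------------------------------

def great_circle_distance(lat1, lon1, lat2, lon2) -> float:
    """Haversine distance in km (Earth radius 6371 km)."""
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    if np.any(np.abs(lat1) > 90) or np.any(np.abs(lat2) > 90) \
            or np.any(np.abs(lon1) > 180) or np.any(np.abs(lon2) > 180):
        raise ValueError("coordinates outside valid ranges")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = np.radians(lat2 - lat1)
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    return d if d.ndim else float(d)


def distance_matrix_km(latitudes, longitudes) -> np.ndarray:
    lat = np.asarray(latitudes, dtype=float)
    lon = np.asarray(longitudes, dtype=float)
    return np.asarray(great_circle_distance(lat[:, None], lon[:, None],
                                            lat[None, :], lon[None, :]))


def spatial_correlation(d, rho: float, kind: str):
    """Between-site correlation at distance ``d`` (km) with range ``rho``.

    exponential: exp(-d/rho); gaussian: exp(-(d/rho)^2);
    rational_quadratic: 1/(1+(d/rho)^2); spherical: 1 - 1.5(d/rho) +
    0.5(d/rho)^3 for d < rho, else 0.
    """
    if rho <= 0:
        raise ValueError("range parameter rho must be > 0")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    r = d / rho
    if kind == "exponential":
        out = np.exp(-r)
    elif kind == "gaussian":
        out = np.exp(-r ** 2)
    elif kind == "rational_quadratic":
        out = 1.0 / (1.0 + r ** 2)
    elif kind == "spherical":
        out = np.where(r < 1.0, 1.0 - 1.5 * r + 0.5 * r ** 3, 0.0)
    else:
        raise ValueError(f"unknown correlation structure {kind!r}")
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

def _restricted_ll(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> tuple:
    """Restricted log-likelihood, GLS beta and its covariance for marginal
    covariance ``V``.  Raises LinAlgError if V is not positive definite."""
    n, m = X.shape
    L = np.linalg.cholesky(V)
    logdetV = 2.0 * np.log(np.diag(L)).sum()
    Li_y = np.linalg.solve(L, y)
    Li_X = np.linalg.solve(L, X)
    XtViX = Li_X.T @ Li_X
    XtViy = Li_X.T @ Li_y
    cov_beta = np.linalg.inv(XtViX)
    beta = cov_beta @ XtViy
    r = Li_y - Li_X @ beta
    quad = float(r @ r)
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    rll = -0.5 * ((n - m) * math.log(2 * math.pi) + logdetV + logdetXtViX + quad)
    return rll, beta, cov_beta, quad


def _rll_diag(y: np.ndarray, X: np.ndarray, diag_v: np.ndarray) -> tuple:
    """Fast path of :func:`_restricted_ll` for diagonal covariance."""
    n, m = X.shape
    w = 1.0 / diag_v
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    XtViX = Xw.T @ Xw
    cov_beta = np.linalg.inv(XtViX)
    beta = cov_beta @ (Xw.T @ yw)
    r = yw - Xw @ beta
    quad = float(r @ r)
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    rll = -0.5 * ((n - m) * math.log(2 * math.pi) + np.log(diag_v).sum()
                  + logdetXtViX + quad)
    return rll, beta, cov_beta, quad


def _fit_core(y: np.ndarray, v: np.ndarray, X: np.ndarray,
              D: np.ndarray | None, structure: str,
              rho: float | None = None) -> dict:
    """REML fit of (tau2, rho) with GLS beta at the optimum."""
    n = len(y)
    if structure != "none" and D is None:
        raise ValueError("spatial structures need a distance matrix (coordinates)")

    resid_var = float(np.var(y, ddof=1)) if n > 1 else 1.0
    tau2_ub = 10.0 * max(resid_var, float(np.max(v)), 1e-3)

    if structure == "none":
        def nll(tau2):
            return -_rll_diag(y, X, v + tau2)[0]
        res = optimize.minimize_scalar(nll, bounds=(0.0, tau2_ub),
                                       method="bounded",
                                       options={"xatol": 1e-10})
        if not res.success:
            raise ConvergenceError("REML optimization failed", trace=res)
        # boundary check: profile down to exactly zero when favourable
        tau2 = float(res.x) if nll(res.x) < nll(0.0) else 0.0
        rll, beta, cov_beta, quad = _rll_diag(y, X, v + tau2)
        return {"tau2": tau2, "rho": None, "rll": rll, "beta": beta,
                "cov_beta": cov_beta, "quad": quad, "k_corr": 1}

    offdiag = D[np.triu_indices(n, 1)]
    pos = offdiag[offdiag > 0]
    med = float(np.median(pos)) if len(pos) else 1.0

    def nll_spatial(params):
        tau2 = math.exp(params[0])
        rho_ = math.exp(params[1]) if rho is None else rho
        R = spatial_correlation(D, rho_, structure)
        V = tau2 * R + np.diag(v)
        try:
            return -_restricted_ll(y, X, V)[0]
        except np.linalg.LinAlgError:
            return 1e12

    tau2_start = max(_fit_core(y, v, X, None, "none")["tau2"], 1e-4)
    best = None
    rho_starts = [med / 4, med, 4 * med] if rho is None else [rho]
    for rho0 in rho_starts:
        x0 = [math.log(tau2_start), math.log(max(rho0, 1e-6))]
        res = optimize.minimize(nll_spatial, x0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10,
                                         "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise ConvergenceError(
            f"REML optimization failed for structure {structure!r}", trace=best)
    tau2 = math.exp(best.x[0])
    rho_hat = math.exp(best.x[1]) if rho is None else rho
    R = spatial_correlation(D, rho_hat, structure)
    V = tau2 * R + np.diag(v)
    try:
        rll, beta, cov_beta, quad = _restricted_ll(y, X, V)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(
            f"singular marginal covariance at the optimum (structure {structure!r}, "
            f"tau2={tau2:.3g}, rho={rho_hat:.3g})") from exc
    return {"tau2": tau2, "rho": rho_hat, "rll": rll, "beta": beta,
            "cov_beta": cov_beta, "quad": quad,
            "k_corr": 1 if rho is not None else 2}


def _heterogeneity_stats(y: np.ndarray, v: np.ndarray, tau2: float) -> dict:
    """Cochran's Q about the fixed-effect mean, and I^2 from the typical
    within-study variance."""
    w = 1.0 / v
    mu_fe = float((w * y).sum() / w.sum())
    Q = float((w * (y - mu_fe) ** 2).sum())
    n = len(y)
    df = n - 1
    Q_p = float(stats.chi2.sf(Q, df)) if df > 0 else math.nan
    s2_typ = (df * w.sum()) / (w.sum() ** 2 - (w ** 2).sum())
    I2 = tau2 / (tau2 + s2_typ) if (tau2 + s2_typ) > 0 else 0.0
    return {"Q": Q, "Q_df": df, "Q_p": Q_p, "I2": float(I2), "s2_typical": float(s2_typ)}


def _aicc(rll: float, k: int, n: int) -> float:
    return -2.0 * rll + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _prepare(effects: pd.DataFrame, structure: str):
    y = effects["g"].to_numpy(dtype=float)
    v = effects["var_g"].to_numpy(dtype=float)
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be > 0")
    D = None
    if structure != "none":
        if not {"latitude", "longitude"}.issubset(effects.columns):
            raise ValueError("spatial structures need latitude/longitude columns")
        D = distance_matrix_km(effects["latitude"], effects["longitude"])
    return y, v, D


def random_effects_fit(effects: pd.DataFrame, structure: str = "none",
                       rho: float | None = None, knha: bool = True) -> MetaFit:
    """Random-effects pooled mean effect size.

    ``effects`` needs columns ``g`` and ``var_g`` (plus ``latitude`` /
    ``longitude`` for spatial structures).  The pooled mean is tested with
    a t reference on n - 1 degrees of freedom; by default the coefficient
    variance carries the Knapp-Hartung small-sample scaling (the residual
    quadratic form over its degrees of freedom), which keeps the t-test
    close to nominal at meta-analytic sample sizes.
    """
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}; choose from {STRUCTURES}")
    n = len(effects)
    if n < 3:
        raise ValueError("need at least three effect sizes")
    y, v, D = _prepare(effects, structure)
    X = np.ones((n, 1))
    core = _fit_core(y, v, X, D, structure, rho=rho)
    mu = float(core["beta"][0])
    scale = core["quad"] / (n - 1) if knha else 1.0
    se = float(math.sqrt(scale * core["cov_beta"][0, 0]))
    df = n - 1
    t = mu / se
    p = float(2 * stats.t.sf(abs(t), df))
    tcrit = float(stats.t.ppf(0.975, df))
    het = _heterogeneity_stats(y, v, core["tau2"])
    k = core["k_corr"] + 1
    return MetaFit(mu=mu, se_mu=se, t=t, df=df, p=p,
                   ci_low=mu - tcrit * se, ci_high=mu + tcrit * se,
                   tau2=core["tau2"], Q=het["Q"], Q_df=het["Q_df"],
                   Q_p=het["Q_p"], I2=het["I2"], structure=structure,
                   rho=core["rho"], rll=core["rll"],
                   aicc=_aicc(core["rll"], k, n), n=n, k_params=k)


def select_structure(effects: pd.DataFrame,
                     candidates=STRUCTURES) -> tuple[MetaFit, pd.DataFrame]:
    """Fit every candidate correlation structure and keep the lowest AICc.

    Returns the winning :class:`MetaFit` and the full comparison table
    (one row per converged candidate, sorted by AICc).
    """
    fits, rows, errors = {}, [], {}
    for cand in candidates:
        try:
            fit = random_effects_fit(effects, structure=cand)
        except (ConvergenceError, ValueError) as exc:
            errors[cand] = str(exc)
            continue
        fits[cand] = fit
        rows.append({"structure": cand, "aicc": fit.aicc, "rll": fit.rll,
                     "tau2": fit.tau2, "rho": fit.rho, "mu": fit.mu})
    if not fits:
        raise ConvergenceError(f"all candidate structures failed: {errors}")
    table = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    return fits[table.loc[0, "structure"]], table


def heterogeneity(effects: pd.DataFrame) -> dict:
    """Q (with df and p), T^2 and I^2 for a set of effect sizes.

    T^2 is the REML estimate with independent random effects; Q is the
    fixed-effect weighted residual sum of squares.
    """
    if len(effects) < 2:
        raise ValueError("need at least two effect sizes")
    y = effects["g"].to_numpy(dtype=float)
    v = effects["var_g"].to_numpy(dtype=float)
    X = np.ones((len(y), 1))
    tau2 = _fit_core(y, v, X, None, "none")["tau2"]
    het = _heterogeneity_stats(y, v, tau2)
    return {"Q": het["Q"], "df": het["Q_df"], "p": het["Q_p"],
            "tau2": tau2, "I2": het["I2"]}


def _vif(M: np.ndarray) -> np.ndarray:
    """Variance inflation factors from the moderator correlation matrix."""
    if M.shape[1] == 1:
        return np.array([1.0])
    R = np.corrcoef(M, rowvar=False)
    cond = np.linalg.cond(R)
    if cond > COLLINEARITY_THRESHOLD:
        raise ValueError(
            f"moderators are collinear (correlation-matrix condition number "
            f"{cond:.3g}); consider summarizing them with a PCA")
    return np.diag(np.linalg.inv(R)).copy()


def meta_regression(effects: pd.DataFrame, moderators: pd.DataFrame,
                    structure: str = "none", rho: float | None = None,
                    knha: bool = True) -> MetaRegressionFit:
    """Random-effects meta-regression of the effect sizes on moderators.

    Coefficients are tested with t references on n - m - 1 degrees of
    freedom (with Knapp-Hartung variance scaling by default); the m
    moderators are tested jointly with an F(m, n - m - 1) Wald test, and
    pseudo-R^2 compares residual T^2 against the intercept-only T^2 under
    the same structure (floored at 0).
    """
    n = len(effects)
    mods = moderators.dropna(axis=0)
    if len(mods) != n:
        raise ValueError("moderators must be complete for every effect size")
    m = mods.shape[1]
    if n <= m + 2:
        raise ValueError(f"need n > m + 2 effect sizes (n={n}, m={m})")
    y, v, D = _prepare(effects, structure)
    M = mods.to_numpy(dtype=float)
    vif = _vif(M)
    X = np.column_stack([np.ones(n), M])
    core = _fit_core(y, v, X, D, structure, rho=rho)
    beta = core["beta"]
    df = n - m - 1
    scale = core["quad"] / df if knha else 1.0
    cov_beta = scale * core["cov_beta"]
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    table = pd.DataFrame({
        "term": ["intercept"] + list(mods.columns),
        "estimate": beta, "se": se, "t": tvals, "df": df, "p": pvals,
        "vif": [math.nan] + list(vif),
    })
    # omnibus Wald F on the m moderator coefficients
    C = cov_beta[1:, 1:]
    b = beta[1:]
    F = float(b @ np.linalg.solve(C, b) / m)
    F_p = float(stats.f.sf(F, m, df))
    fit0 = _fit_core(y, v, np.ones((n, 1)), D, structure, rho=rho)
    tau2_0, tau2_1 = fit0["tau2"], core["tau2"]
    pseudo = max(0.0, (tau2_0 - tau2_1) / tau2_0) if tau2_0 > 0 else 0.0
    k = core["k_corr"] + 1 + m
    return MetaRegressionFit(table=table, F=F, F_df=(m, df), F_p=F_p,
                             pseudo_R2=pseudo, tau2=tau2_1,
                             tau2_intercept_only=tau2_0,
                             structure=structure, rho=core["rho"],
                             rll=core["rll"], aicc=_aicc(core["rll"], k, n),
                             n=n, moderators=list(mods.columns))


# ---------------------------------------------------------------------------
# Paired Wilcoxon comparisons
# ---------------------------------------------------------------------------

def paired_wilcoxon(values_low, values_high) -> tuple[float, float]:
    """Two-tailed Wilcoxon signed-rank test on paired per-landscape values.

    Zero differences are dropped; the exact permutation null is used for
    n <= 25 tie-free differences, otherwise the normal approximation with
    continuity correction.  Returns (statistic, p).
    """
    low = np.asarray(values_low, dtype=float)
    high = np.asarray(values_high, dtype=float)
    if low.shape != high.shape:
        raise ValueError("paired samples must have equal length")
    d = low - high
    d = d[d != 0]
    if len(d) == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    if len(d) < 5:
        raise ValueError("need at least five non-zero paired differences")
    ties = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= 25 and not ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"),
                         alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
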