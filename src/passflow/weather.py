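"""Daily-count weather model: ZINB regression with a cauchit zero link.

The daily number of migrants through the pass is modelled as a zero-inflated
negative binomial.  A day is a structural zero (no migration attempted) with
probability ``pi = F(z'gamma)`` where ``F`` is the inverse cauchit link
``F(eta) = 1/2 + arctan(eta)/pi`` — heavier-tailed than the logistic, which
suits the abrupt all-or-nothing character of migration days.  Otherwise the
count is NB2 with mean ``mu = exp(x'beta)`` and dispersion ``theta``
(``Var = mu + mu^2/theta``).

Covariates follow the monitoring protocol: headwind index ``h`` in [-1, 1]
(cosine of the angle between the wind's "from" bearing and the full-headwind
bearing), rainfall (mm), sunshine proportion ``s`` in [0, 1], temperature
(deg C) and windspeed (m/s), with pairwise interactions.  Model search is
all-subsets by AIC with the count and zero parts treated separately, and
variable importance is the mean AIC of each candidate over all fixed-size
subsets containing it.  Uncertainty of prediction curves comes from a
nonparametric day-resampling bootstrap.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "derive_covariates", "build_design", "cauchit", "zinb_loglik",
    "fit_zinb", "predict_expected", "all_subsets_select",
    "importance_ranking", "bootstrap_predictions", "ZINBFit",
]

#: model term -> weather-table column
TERM_COLUMNS = {
    "headwind": "h",
    "rainfall": "rain_mm",
    "sunshine": "s",
    "temperature": "temp_c",
    "windspeed": "windspeed_ms",
}

#: candidate interactions considered by default (pairs of main terms)
DEFAULT_INTERACTIONS = (
    ("headwind", "windspeed"),
    ("sunshine", "temperature"),
    ("sunshine", "rainfall"),
)


def derive_covariates(weather: pd.DataFrame, headwind_bearing_deg: float = 225.0,
                      sunshine_window_min: float = 480.0) -> pd.DataFrame:
    """Add the headwind index ``h`` and sunshine proportion ``s``.

    ``h = cos(wind_heading - headwind_bearing)``: +1 when the wind blows
    straight from the migrants' destination bearing (full headwind for
    southwest-bound flight with the default 225 deg), -1 for a full
    tailwind.  ``s = sunshine_min / sunshine_window_min`` clipped to [0, 1];
    the default window is the 480-min observation day (09:00-17:00).
    """
    out = weather.copy()
    heading = np.asarray(out["wind_heading_deg"], dtype=float)
    if np.any((heading < 0) | (heading >= 360)):
        heading = np.mod(heading, 360.0)
        out["wind_heading_deg"] = heading
    out["h"] = np.cos(np.deg2rad(heading - headwind_bearing_deg))
    out["s"] = np.clip(
        np.asarray(out["sunshine_min"], dtype=float) / sunshine_window_min,
        0.0, 1.0)
    return out


def _term_values(df: pd.DataFrame, term: str) -> np.ndarray:
    if term == "intercept":
        return np.ones(len(df))
    if ":" in term:
        a, b = term.split(":")
        return _term_values(df, a) * _term_values(df, b)
    col = TERM_COLUMNS.get(term, term)
    if col not in df.columns:
        raise KeyError(f"covariate column for term {term!r} "
                       f"({col!r}) not found")
    return np.asarray(df[col], dtype=float)


def build_design(df: pd.DataFrame, terms) -> tuple:
    """Build a design matrix (intercept first) for the named terms.

    Returns ``(X, names)`` where ``names[0] == 'intercept'``.  Interaction
    terms are written ``a:b`` and computed as elementwise products.
    """
    names = ["intercept"] + [t for t in terms if t != "intercept"]
    X = np.column_stack([_term_values(df, t) for t in names])
    if not np.all(np.isfinite(X)):
        raise ValueError("design contains non-finite values")
    return X, names


def cauchit(eta):
    """Inverse cauchit link: P(structural zero) = 1/2 + arctan(eta)/pi."""
    return 0.5 + np.arctan(eta) / np.pi


def _inv_link(eta, zero_link):
    if zero_link == "cauchit":
        return cauchit(eta)
    if zero_link == "logit":
        return special.expit(eta)
    raise ValueError(f"unknown zero link {zero_link!r}")


def _nb_logpmf(y, mu, theta):
    # NB2 log pmf via gamma functions; stable for real-valued theta
    return (special.gammaln(y + theta) - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * (np.log(theta) - np.log(theta + mu))
            + y * (np.log(mu) - np.log(theta + mu)))


def zinb_loglik(y, X, Z, beta, gamma, theta,
                zero_link: str = "cauchit") -> float:
    """Log-likelihood of the ZINB model.

    ``l = sum_i log[ pi_i 1(y_i=0) + (1 - pi_i) NB(y_i; mu_i, theta) ]``
    with ``mu_i = exp(x_i'beta)`` and ``pi_i`` from the inverse zero link
    (cauchit by default, logit available for comparison), evaluated in log
    space.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Z))):
        raise ValueError("design contains non-finite values")
    if theta <= 0:
        raise ValueError("theta must be positive")
    eta_mu = np.clip(X @ np.asarray(beta, dtype=float), -500, 500)
    mu = np.exp(eta_mu)
    eta_pi = Z @ np.asarray(gamma, dtype=float)
    pi = _inv_link(eta_pi, zero_link)
    # keep log(pi), log(1-pi) finite; cauchit never reaches 0/1 exactly
    log_pi = np.log(np.clip(pi, 1e-300, 1.0))
    log_1mpi = np.log(np.clip(1.0 - pi, 1e-300, 1.0))
    nb = _nb_logpmf(y, mu, theta)
    zero = y == 0
    ll = np.empty_like(y)
    # y=0: logsumexp of the two mixture branches
    ll[zero] = np.logaddexp(log_pi[zero], log_1mpi[zero] + nb[zero])
    ll[~zero] = log_1mpi[~zero] + nb[~zero]
    return float(np.sum(ll))


@dataclass
class ZINBFit:
    """A fitted zero-inflated negative-binomial regression.

    ``beta``/``gamma`` are pandas Series indexed by term name (count part on
    the log scale, zero part on the cauchit scale); ``theta`` the NB
    dispersion.  ``vcov`` covers the packed parameter vector
    ``(beta, gamma, log theta)``; standard errors, z- and p-values are Wald.
    """

    beta: pd.Series
    gamma: pd.Series
    theta: float
    loglik: float
    aic: float
    converged: bool
    vcov: pd.DataFrame = None
    n_obs: int = 0

    @property
    def k_params(self) -> int:
        return len(self.beta) + len(self.gamma) + 1

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov)), index=self.vcov.index)

    def coef_table(self) -> pd.DataFrame:
        """Coefficient table (estimate, SE, z, p) for both model parts."""
        est = pd.concat([
            self.beta.rename(lambda t: f"count:{t}"),
            self.gamma.rename(lambda t: f"zero:{t}"),
        ])
        se = self.se.reindex(est.index)
        z = est / se
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame({"estimate": est, "std_error": se,
                             "z_value": z, "p_value": p})


def _pack(beta, gamma, log_theta):
    return np.concatenate([beta, gamma, [log_theta]])


def _start_values(y, X, Z):
    # count part: least squares on log(y+1); robust, deterministic
    beta0, *_ = np.linalg.lstsq(X, np.log(np.asarray(y) + 1.0), rcond=None)
    p0 = float(np.clip(np.mean(np.asarray(y) == 0), 0.05, 0.95))
    gamma0 = np.zeros(Z.shape[1])
    gamma0[0] = math.tan(math.pi * (p0 - 0.5))
    return beta0, gamma0, 0.0


def fit_zinb(y, X, Z, beta_names=None, gamma_names=None,
             maxiter: int = 500, zero_link: str = "cauchit",
             start=None, thorough: bool = True) -> ZINBFit:
    """Maximum-likelihood fit of the ZINB model with cauchit zero link.

    Optimizes ``(beta, gamma, log theta)`` by L-BFGS-B from deterministic
    starting values (log-linear least squares for ``beta``; the cauchit
    inverse of the observed zero fraction for the ``gamma`` intercept),
    retrying from perturbed zero-part starts if the first attempt fails.
    The covariance matrix is the inverse numerical Hessian at the optimum.

    ``start`` warm-starts the optimizer at a packed ``(beta, gamma,
    log theta)`` vector; with ``thorough=False`` the multi-start grid and
    simplex polishing are skipped (one quasi-Newton run), the intended mode
    for bootstrap refits from the point estimate.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if np.all(y == 0):
        raise ValueError("all counts are zero; the count part is "
                         "unidentifiable")
    if not np.any(y == 0):
        raise ValueError("no zero counts; fit a plain NB model instead")
    p, q = X.shape[1], Z.shape[1]
    beta_names = list(beta_names) if beta_names is not None else [
        f"x{i}" for i in range(p)]
    gamma_names = list(gamma_names) if gamma_names is not None else [
        f"z{i}" for i in range(q)]

    def negll(params):
        beta, gamma = params[:p], params[p:p + q]
        theta = math.exp(min(params[-1], 30.0))
        try:
            return -zinb_loglik(y, X, Z, beta, gamma, theta, zero_link)
        except (ValueError, FloatingPointError):
            return 1e12

    if start is not None:
        starts = [np.asarray(start, dtype=float)]
    else:
        beta0, gamma0, _ = _start_values(y, X, Z)
        if zero_link == "logit":
            p0 = float(np.clip(np.mean(y == 0), 0.05, 0.95))
            gamma0[0] = math.log(p0 / (1 - p0))
        # multi-start over the dispersion scale plus perturbed zero-part
        # intercepts: the mixture likelihood is multimodal in (gamma, theta)
        starts = [_pack(beta0, gamma0, lt0) for lt0 in (-1.0, 0.0, 1.0)]
        for shift in (2.0, -2.0):
            g = gamma0.copy()
            g[0] += shift
            starts.append(_pack(beta0, g, 0.0))

    lbfgs_opts = {"maxiter": maxiter, "maxfun": 100000,
                  "ftol": 1e-12, "gtol": 1e-8}
    fun, x = np.inf, None
    for x0 in starts:
        res = optimize.minimize(negll, x0, method="L-BFGS-B",
                                options=lbfgs_opts)
        if res.fun < fun:
            fun, x = res.fun, res.x
    # alternate simplex and quasi-Newton until neither improves: the
    # simplex rescues line-search stalls near likelihood ridges, and a
    # final failed-to-improve probe certifies stationarity
    stationary = not thorough and bool(res.success)
    for _ in range(3 if thorough else 0):
        probe = optimize.minimize(negll, x, method="Nelder-Mead",
                                  options={"maxiter": 4000, "xatol": 1e-8,
                                           "fatol": 1e-10})
        if probe.fun < fun - 1e-6:
            fun, x = probe.fun, probe.x
            res = optimize.minimize(negll, x, method="L-BFGS-B",
                                    options=lbfgs_opts)
            if res.fun < fun:
                fun, x = res.fun, res.x
        else:
            if probe.fun < fun:
                fun, x = probe.fun, probe.x
            stationary = True
            break

    params = x
    beta = pd.Series(params[:p], index=beta_names)
    gamma = pd.Series(params[p:p + q], index=gamma_names)
    theta = math.exp(params[-1])
    ll = -fun
    k = p + q + 1
    aic = 2 * k - 2 * ll

    from statsmodels.tools.numdiff import approx_hess
    names = ([f"count:{t}" for t in beta_names]
             + [f"zero:{t}" for t in gamma_names] + ["log_theta"])
    vcov = pd.DataFrame(np.full((k, k), np.nan), index=names, columns=names)
    converged = stationary and fun < 1e11
    try:
        H = approx_hess(params, negll)
        vc = np.linalg.inv(H)
        if np.all(np.diag(vc) > 0):
            vcov = pd.DataFrame(vc, index=names, columns=names)
        else:
            converged = False
    except np.linalg.LinAlgError:
        converged = False
    return ZINBFit(beta=beta, gamma=gamma, theta=theta, loglik=ll, aic=aic,
                   converged=converged, vcov=vcov, n_obs=len(y))


def fit_zinb_terms(data: pd.DataFrame, count_terms, zero_terms,
                   y_col: str = "total_count", **kw) -> ZINBFit:
    """Fit the ZINB model from named terms on a covariate table."""
    X, bn = build_design(data, count_terms)
    Z, gn = build_design(data, zero_terms)
    return fit_zinb(np.asarray(data[y_col]), X, Z, bn, gn, **kw)


def predict_expected(fit: ZINBFit, data: pd.DataFrame) -> np.ndarray:
    """Expected daily count ``(1 - pi) * mu`` on new covariate rows."""
    X, _ = build_design(data, [t for t in fit.beta.index if t != "intercept"])
    Z, _ = build_design(data, [t for t in fit.gamma.index if t != "intercept"])
    mu = np.exp(np.clip(X @ fit.beta.values, -500, 500))
    pi = cauchit(Z @ fit.gamma.values)
    return (1.0 - pi) * mu


def _admissible(subset, marginality: bool) -> bool:
    if not marginality:
        return True
    present = set(subset)
    for t in subset:
        if ":" in t:
            a, b = t.split(":")
            if a not in present or b not in present:
                return False
    return True


def all_subsets_select(data: pd.DataFrame, count_candidates, zero_candidates,
                       y_col: str = "total_count", marginality: bool = True,
                       cap: int = 4096):
    """All-subsets AIC search over count-part x zero-part term sets.

    Fits every admissible pair of subsets (interactions require both
    parents when ``marginality`` is on; the empty subset is the
    intercept-only part).  Returns ``(best_fit, table)`` with the model
    table sorted by AIC.
    """
    for cand in (count_candidates, zero_candidates):
        if len(set(cand)) != len(list(cand)):
            raise ValueError("duplicate candidate names")
    count_sets = [s for r in range(len(count_candidates) + 1)
                  for s in itertools.combinations(count_candidates, r)
                  if _admissible(s, marginality)]
    zero_sets = [s for r in range(len(zero_candidates) + 1)
                 for s in itertools.combinations(zero_candidates, r)
                 if _admissible(s, marginality)]
    n_models = len(count_sets) * len(zero_sets)
    if n_models > cap:
        raise ValueError(
            f"enumeration would fit {n_models} models (cap {cap}); "
            "restrict the candidate lists or raise the cap")
    rows = []
    best = None
    for cs in count_sets:
        for zs in zero_sets:
            fit = fit_zinb_terms(data, list(cs), list(zs), y_col=y_col)
            rows.append({"count_terms": "+".join(cs) or "1",
                         "zero_terms": "+".join(zs) or "1",
                         "k": fit.k_params, "loglik": fit.loglik,
                         "aic": fit.aic, "converged": fit.converged})
            if best is None or fit.aic < best.aic:
                best = fit
    table = (pd.DataFrame(rows).sort_values("aic", kind="mergesort")
             .reset_index(drop=True))
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return best, table


def importance_ranking(data: pd.DataFrame, candidates, sizes=(3,),
                       interactions=DEFAULT_INTERACTIONS,
                       y_col: str = "total_count",
                       mirror_zero: bool = False) -> pd.DataFrame:
    """Rank candidate variables by mean AIC over fixed-size subsets.

    For each candidate, every subset of each size in ``sizes`` containing it
    is fitted (adding any listed interaction whose two parents are both in
    the subset) and its AICs averaged; lower mean AIC ranks higher.  With 7
    candidates and size 3, each candidate appears in C(6,2)=15 models.  The
    subset enters the count part; the zero part is intercept-only unless
    ``mirror_zero``.
    """
    candidates = list(candidates)
    if len(set(candidates)) != len(candidates):
        raise ValueError("duplicate candidate names")
    if max(sizes) > len(candidates):
        raise ValueError("subset size exceeds candidate pool")
    inter = {frozenset(p): f"{p[0]}:{p[1]}" for p in interactions}
    aic_cache: dict = {}

    def model_aic(subset) -> float:
        key = frozenset(subset)
        if key not in aic_cache:
            terms = list(subset)
            for pair, name in inter.items():
                if pair <= set(subset):
                    terms.append(name)
            zero_terms = terms if mirror_zero else []
            fit = fit_zinb_terms(data, terms, zero_terms, y_col=y_col)
            aic_cache[key] = fit.aic
        return aic_cache[key]

    rows = []
    for cand in candidates:
        aics = [model_aic(sub)
                for k in sizes
                for sub in itertools.combinations(candidates, k)
                if cand in sub]
        rows.append({"term": cand, "mean_aic": float(np.mean(aics)),
                     "n_models": len(aics)})
    out = pd.DataFrame(rows).sort_values(
        "mean_aic", kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def bootstrap_predictions(data: pd.DataFrame, count_terms, zero_terms,
                          focal: str, B: int = 999, seed: int = 0,
                          grid: np.ndarray = None, grid_size: int = 25,
                          y_col: str = "total_count"):
    """Bootstrap 95% bands for the expected-count curve along one covariate.

    Days are resampled with replacement and the model refitted; predictions
    put every other covariate at its observed median.  Returns a DataFrame
    (focal value, point prediction, 2.5/97.5 percentiles) with a
    ``bootstrap_warning`` attribute set when more than 20% of refits failed
    to converge.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    col = TERM_COLUMNS.get(focal, focal)
    if grid is None:
        grid = np.linspace(data[col].min(), data[col].max(), grid_size)
    med = data.median(numeric_only=True)
    grid_df = pd.DataFrame({c: np.full(len(grid), med[c])
                            for c in data.columns
                            if c in med.index})
    grid_df[col] = grid

    point_fit = fit_zinb_terms(data, count_terms, zero_terms, y_col=y_col)
    point = predict_expected(point_fit, grid_df)
    warm = np.concatenate([point_fit.beta.to_numpy(),
                           point_fit.gamma.to_numpy(),
                           [math.log(point_fit.theta)]])

    rng = np.random.default_rng(seed)
    preds = np.empty((B, len(grid)))
    n_bad = 0
    n = len(data)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        boot = data.iloc[idx].reset_index(drop=True)
        try:
            # warm-started single quasi-Newton run: each resample's optimum
            # lies near the full-data one
            fit = fit_zinb_terms(boot, count_terms, zero_terms, y_col=y_col,
                                 start=warm, thorough=False)
            if not fit.converged:
                n_bad += 1
            preds[b] = predict_expected(fit, grid_df)
        except (ValueError, np.linalg.LinAlgError):
            n_bad += 1
            preds[b] = np.nan
    lo, hi = np.nanpercentile(preds, [2.5, 97.5], axis=0)
    out = pd.DataFrame({col: grid, "predicted": point,
                        "lower_95": lo, "upper_95": hi})
    out.attrs["bootstrap_warning"] = n_bad > 0.2 * B
    out.attrs["n_nonconverged"] = n_bad
    return out
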