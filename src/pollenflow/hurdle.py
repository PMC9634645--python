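"""Hurdle count regression of dye transfers by maximum likelihood.

The model has two parts sharing no parameters, so the log-likelihood
separates and the parts are fitted independently:

* a logit model for crossing the hurdle (any dye at all on a recipient),
* a zero-truncated Poisson or negative-binomial (NB2) model for the
  summed dye count of recipients that did receive dye, with
  log(number of sampled flowers) as an offset.

Formulas use the patsy grammar (e.g. ``"r + total_flowers_est +
C(transfer_class) + r:C(transfer_class)"``). Continuous design columns
are standardized internally for optimizer stability and coefficients,
standard errors and the covariance are mapped back to the original
scale before reporting. Standard errors come from the numerically
evaluated observed information at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, stats
from scipy.special import expit, gammaln
from statsmodels.tools.numdiff import approx_hess

__all__ = ["HurdleSpec", "HurdleFit", "fit_hurdle", "likelihood_ratio_test",
           "quantile_residuals", "run_transfer_analyses"]

_MAX_ABS_LOGIT_COEF = 30.0  # |standardized coef| beyond this signals separation


@dataclass
class HurdleSpec:
    """Model specification: formulas per component, offset column, family."""

    zero_formula: str
    count_formula: str
    response: str = "sum_count"
    offset: str | None = "n_flowers_sampled"  # enters the count part as log(offset)
    family: str = "negbin"

    def __post_init__(self) -> None:
        if self.family not in ("poisson", "negbin"):
            raise ValueError(f"family must be 'poisson' or 'negbin', got {self.family!r}")


@dataclass
class HurdleFit:
    zero_coefs: pd.Series
    count_coefs: pd.Series
    zero_se: pd.Series
    count_se: pd.Series
    loglik: float
    loglik_zero: float
    loglik_count: float
    family: str
    nb_size: float | None
    converged: bool
    n_obs: int
    spec: HurdleSpec
    message: str = ""
    _data: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def z_stats(self) -> pd.Series:
        return pd.concat([self.zero_coefs / self.zero_se,
                          self.count_coefs / self.count_se])

    @property
    def p_values(self) -> pd.Series:
        return 2.0 * pd.Series(stats.norm.sf(np.abs(self.z_stats)),
                               index=self.z_stats.index)

    @property
    def n_params(self) -> int:
        k = len(self.zero_coefs) + len(self.count_coefs)
        return k + (1 if self.family == "negbin" else 0)

    def tidy(self) -> pd.DataFrame:
        """Coefficient table: term, component, estimate, SE, Wald z, two-sided p."""
        rows = []
        for comp, coefs, ses in (("zero", self.zero_coefs, self.zero_se),
                                 ("count", self.count_coefs, self.count_se)):
            for term in coefs.index:
                z = coefs[term] / ses[term]
                rows.append({"term": term, "component": comp,
                             "estimate": coefs[term], "se": ses[term],
                             "z": z, "p": 2.0 * stats.norm.sf(abs(z))})
        if self.family == "negbin":
            rows.append({"term": "nb_size", "component": "count",
                         "estimate": self.nb_size, "se": np.nan,
                         "z": np.nan, "p": np.nan})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------- internals

def _standardize(X: np.ndarray):
    """Standardize non-constant columns; return (Xs, transform to original scale).

    theta_orig = T @ theta_std where T folds the column means into the
    intercept and divides slopes by their standard deviations.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    means = X.mean(axis=0)
    stds = X.std(axis=0, ddof=0)
    const_cols = stds < 1e-12
    stds_eff = np.where(const_cols, 1.0, stds)
    means_eff = np.where(const_cols, 0.0, means)
    Xs = (X - means_eff) / stds_eff
    intercept_idx = np.flatnonzero(const_cols)
    T = np.diag(1.0 / stds_eff)
    if intercept_idx.size:
        i0 = intercept_idx[0]
        c0 = X[0, i0]  # constant column value (patsy intercept = 1)
        T[i0, :] = -means_eff / (stds_eff * c0)
        T[i0, i0] = 1.0 / c0
    return Xs, T


def _logit_loglik(theta, X, y01):
    eta = X @ theta
    # log(1+e^eta) stably
    return float(np.sum(y01 * eta - np.logaddexp(0.0, eta)))


def _fit_logit(X: np.ndarray, y01: np.ndarray, max_iter: int = 100):
    """Newton-Raphson with step halving; returns (theta, converged, message)."""
    n, p = X.shape
    theta = np.zeros(p)
    ll = _logit_loglik(theta, X, y01)
    message = ""
    for _ in range(max_iter):
        mu = expit(X @ theta)
        grad = X.T @ (y01 - mu)
        wdiag = np.maximum(mu * (1 - mu), 1e-10)
        hess = (X * wdiag[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return theta, False, "singular information matrix in logit part"
        for _ in range(30):
            cand = theta + step
            ll_new = _logit_loglik(cand, X, y01)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        theta, ll_old, ll = cand, ll, ll_new
        if np.max(np.abs(grad)) < 1e-8 or abs(ll - ll_old) < 1e-12:
            break
    if np.max(np.abs(theta)) > _MAX_ABS_LOGIT_COEF:
        return theta, False, ("apparent complete separation in the zero part: "
                              "coefficients diverging")
    return theta, True, message


def _trunc_count_negll(params, X, y, log_off, family):
    """Negative log-likelihood of the zero-truncated count part.

    ``params`` = (beta, log k) for negbin, beta for poisson; y >= 1.
    """
    if family == "negbin":
        beta, logk = params[:-1], params[-1]
        k = np.exp(logk)
    else:
        beta = params
    eta = X @ beta + log_off
    eta = np.clip(eta, -30.0, 30.0)
    mu = np.exp(eta)
    if family == "poisson":
        logp0 = -mu
        ll = y * eta - mu - gammaln(y + 1)
    else:
        logp0 = k * (np.log(k) - np.log(k + mu))
        ll = (gammaln(y + k) - gammaln(k) - gammaln(y + 1)
              + k * np.log(k / (k + mu)) + y * (eta - np.log(k + mu)))
    # truncation: divide by P(Y >= 1)
    ll -= np.log1p(-np.exp(np.minimum(logp0, -1e-12)))
    return -float(np.sum(ll))


def _fit_truncated_count(X, y, log_off, family, seed):
    """L-BFGS-B from a moment start with jittered restarts."""
    n, p = X.shape
    rng = np.random.default_rng(seed)
    # moment start: log-linear regression of log y on X (offset removed)
    z = np.log(y) - log_off
    beta0, *_ = np.linalg.lstsq(X, z, rcond=None)
    start = np.concatenate([beta0, [0.0]]) if family == "negbin" else beta0
    best = None
    for attempt in range(4):
        x0 = start if attempt == 0 else start + rng.normal(0, 0.5, size=start.shape)
        res = optimize.minimize(_trunc_count_negll, x0, args=(X, y, log_off, family),
                                method="L-BFGS-B")
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if res.success and attempt >= 0 and best.success:
            break
    return best


def build_design(data: pd.DataFrame, formula: str) -> tuple[np.ndarray, list[str]]:
    dm = patsy.dmatrix("1 + " + formula, data, return_type="dataframe")
    return dm.to_numpy(), list(dm.columns)


def fit_hurdle(data: pd.DataFrame, spec: HurdleSpec, seed: int = 0) -> HurdleFit:
    """Fit the hurdle model; the two parts are maximized independently."""
    data = data.reset_index(drop=True)
    y = np.asarray(data[spec.response], dtype=float)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("response must be non-negative integer counts")
    if len(y) < 10:
        raise ValueError("need at least 10 observations")
    if np.all(y > 0):
        raise ValueError("no zeros: hurdle unidentified")
    if np.all(y == 0):
        raise ValueError("all counts zero: count component unidentified")

    Xz, zero_names = build_design(data, spec.zero_formula)
    Xc, count_names = build_design(data, spec.count_formula)
    log_off = (np.log(np.asarray(data[spec.offset], dtype=float))
               if spec.offset else np.zeros(len(y)))

    y01 = (y > 0).astype(float)
    Xz_s, Tz = _standardize(Xz)
    theta_z, conv_z, msg_z = _fit_logit(Xz_s, y01)
    ll_zero = _logit_loglik(theta_z, Xz_s, y01)

    pos = y > 0
    Xc_pos = Xc[pos]
    Xc_s, Tc = _standardize(Xc_pos)
    res = _fit_truncated_count(Xc_s, y[pos], log_off[pos], spec.family, seed)
    ll_count = -res.fun
    conv_c = bool(res.success)

    # observed-information covariance in the standardized space
    hz = approx_hess(theta_z, lambda t: -_logit_loglik(t, Xz_s, y01))
    cov_z_std = _safe_inv(hz)
    hc = approx_hess(res.x, _trunc_count_negll,
                     args=(Xc_s, y[pos], log_off[pos], spec.family))
    cov_c_std_full = _safe_inv(hc)

    pz = Xz.shape[1]
    pc = Xc.shape[1]
    coef_z = Tz @ theta_z
    cov_z = Tz @ cov_z_std @ Tz.T
    beta_c_std = res.x[:pc]
    cov_beta_std = cov_c_std_full[:pc, :pc]
    coef_c = Tc @ beta_c_std
    cov_c = Tc @ cov_beta_std @ Tc.T
    nb_size = float(np.exp(res.x[-1])) if spec.family == "negbin" else None

    return HurdleFit(
        zero_coefs=pd.Series(coef_z, index=zero_names),
        count_coefs=pd.Series(coef_c, index=count_names),
        zero_se=pd.Series(np.sqrt(np.maximum(np.diag(cov_z), 0.0)), index=zero_names),
        count_se=pd.Series(np.sqrt(np.maximum(np.diag(cov_c), 0.0)), index=count_names),
        loglik=ll_zero + ll_count, loglik_zero=ll_zero, loglik_count=ll_count,
        family=spec.family, nb_size=nb_size,
        converged=conv_z and conv_c, n_obs=len(y), spec=spec,
        message="; ".join(m for m in (msg_z, "" if conv_c else "count part: " + res.message)
                          if m),
        _data=data)


def _safe_inv(h: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(h)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(h)


def likelihood_ratio_test(full: HurdleFit, reduced: HurdleFit):
    """LR test of nested hurdle fits: 2*(ll_full - ll_reduced) ~ chi2(df)."""
    if full.n_obs != reduced.n_obs:
        raise ValueError("fits are on different data (n_obs differ)")
    if not (set(reduced.zero_coefs.index) <= set(full.zero_coefs.index)
            and set(reduced.count_coefs.index) <= set(full.count_coefs.index)):
        raise ValueError("reduced model is not nested in the full model")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("'full' model has fewer parameters than 'reduced'")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if df == 0:
        return 0.0, 0, 1.0
    return stat, df, float(stats.chi2.sf(stat, df))


def _hurdle_cdf_grid(fit: HurdleFit, data: pd.DataFrame):
    """Per-observation P(Y = 0) and truncated-count distribution pieces."""
    Xz, _ = build_design(data, fit.spec.zero_formula)
    Xc, _ = build_design(data, fit.spec.count_formula)
    log_off = (np.log(np.asarray(data[fit.spec.offset], dtype=float))
               if fit.spec.offset else np.zeros(len(data)))
    p_pos = expit(Xz @ fit.zero_coefs.to_numpy())
    mu = np.exp(np.clip(Xc @ fit.count_coefs.to_numpy() + log_off, -30, 30))
    return p_pos, mu


def quantile_residuals(fit: HurdleFit, data: pd.DataFrame | None = None,
                       seed: int = 0) -> np.ndarray:
    """Randomized quantile residuals under the fitted hurdle model.

    The fitted CDF evaluated just below and at each observed count
    brackets a uniform draw which is mapped through the standard-normal
    quantile function; well-specified fits give approximately iid
    standard-normal residuals.
    """
    data = fit._data if data is None else data
    if data is None:
        raise ValueError("fit carries no data; pass the data frame explicitly")
    y = np.asarray(data[fit.spec.response], dtype=float)
    p_pos, mu = _hurdle_cdf_grid(fit, data)
    if fit.family == "poisson":
        p0 = np.exp(-mu)
        cdf = lambda q: stats.poisson.cdf(q, mu)
    else:
        k = fit.nb_size
        p0 = (k / (k + mu)) ** k
        cdf = lambda q: stats.nbinom.cdf(q, k, k / (k + mu))

    def hurdle_cdf(q):
        out = np.where(q < 0, 0.0, 1.0 - p_pos)
        with np.errstate(divide="ignore", invalid="ignore"):
            trunc = (cdf(np.maximum(q, 0)) - p0) / (1.0 - p0)
        return np.where(q < 0, 0.0, out + p_pos * np.clip(trunc, 0.0, 1.0))

    rng = np.random.default_rng(seed)
    lo = hurdle_cdf(y - 1)
    hi = hurdle_cdf(y)
    u = lo + rng.uniform(size=len(y)) * np.maximum(hi - lo, 1e-12)
    return stats.norm.ppf(np.clip(u, 1e-10, 1 - 1e-10))


ANALYSES = ("intrapop_differences", "intra_vs_inter_ecotypic", "directionality")


def run_transfer_analyses(transfers: pd.DataFrame, which: str,
                          family: str = "negbin",
                          exclude: list[str] | None = None,
                          seed: int = 0,
                          residual_check: bool = True):
    """The three transfer analyses as hurdle fits on the transfer table.

    1. ``intrapop_differences`` — intrapopulation records; population as
       the nominal predictor.
    2. ``intra_vs_inter_ecotypic`` — interpopulation records; transfer
       class (intra- vs inter-ecotypic) as the nominal predictor.
    3. ``directionality`` — inter-ecotypic records only; direction
       (CaToSi vs SiToCa) as the nominal predictor.

    Each model has distance, estimated total flowers, the nominal term
    and its interaction with distance in both components, with
    log(sampled flowers) offsetting the count part. ``exclude`` removes
    listed recipient ids first (manual outlier handling only).

    Returns ``(HurdleFit, tidy coefficient table, MoranResult or None)``.
    """
    if which not in ANALYSES:
        raise ValueError(f"unknown analysis {which!r}; choose from {ANALYSES}")
    df = transfers.copy()
    if exclude:
        df = df[~df["recipient_id"].isin(exclude)]
    if which == "intrapop_differences":
        df = df[df["transfer_class"] == "intrapopulation"]
        nominal = "recipient_population"
    elif which == "intra_vs_inter_ecotypic":
        df = df[df["transfer_class"].isin(["intra_ecotypic", "inter_ecotypic"])]
        nominal = "transfer_class"
    else:
        df = df[df["transfer_class"] == "inter_ecotypic"]
        if df.empty or df["direction"].nunique() < 2:
            raise ValueError("directionality analysis requires inter-ecotypic "
                             "transfers in both directions")
        nominal = "direction"
    df = df.dropna(subset=["total_flowers_est"]).reset_index(drop=True)
    formula = f"r + total_flowers_est + C({nominal}) + r:C({nominal})"
    spec = HurdleSpec(zero_formula=formula, count_formula=formula, family=family)
    fit = fit_hurdle(df, spec, seed=seed)
    moran = None
    if residual_check and {"x", "y"} <= set(df.columns):
        from pollenflow.spatial import residual_spatial_check
        resid = quantile_residuals(fit, df, seed=seed)
        coords = df[["x", "y"]].to_numpy()
        moran = residual_spatial_check(resid, coords, seed=seed)
    return fit, fit.tidy(), moran
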