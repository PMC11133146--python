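"""Confirmatory count-model pipeline for entries under manipulation.

The dependent variable — the number of app entries a participant commits
after a warehouse manipulation message — is modelled with mixed-effects
count regressions of the form

    entries ~ manipulation * group + (1 | participant)

with reference levels control_pre and short training.  Daily entry
counts are strongly overdispersed, so beyond the Poisson mixed model the
module fits three candidates that absorb overdispersion: an
observation-level random-effects model (OLRE: Poisson with an extra
per-observation normal intercept), NB1 (negative binomial with linear
"quasi-Poisson" variance mu*(1+alpha)) and NB2 (quadratic variance
mu + mu^2/theta).  Marginal likelihoods integrate the participant
intercept by adaptive Gauss-Hermite quadrature; model choice uses
leave-one-out cross-validation by mean squared error; habit-subgroup
structure in the adaptation index is probed with univariate Gaussian
mixtures selected by BIC; engagement analyses use Jaeckel rank-based
regression with Wilcoxon scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats
from sklearn.mixture import GaussianMixture

__all__ = [
    "MixedCountFit",
    "MixtureFit",
    "RankRegressionFit",
    "build_design",
    "fit_mixed_count",
    "dispersion_ratio",
    "dispersion_ratio_from_chi2",
    "loocv_select",
    "interaction_tests",
    "fit_mixture",
    "select_k",
    "rank_regression",
    "nb1_variance",
    "nb2_variance",
]

FAMILIES = ("poisson", "olre", "nb1", "nb2")

MANIPULATION_LEVELS = ("control_pre", "devaluation", "control_post")
GROUP_LEVELS = ("short", "extensive", "extensive_parallel")

_GROUP_LABEL = {"extensive": "Extensive",
                "extensive_parallel": "ExtensiveParallel"}
_MANIP_LABEL = {"devaluation": "Devaluation", "control_post": "ControlPost"}


def nb1_variance(mu: float, alpha: float) -> float:
    """Linear ("quasi-Poisson") variance mu * (1 + alpha)."""
    return mu * (1.0 + alpha)


def nb2_variance(mu: float, theta: float) -> float:
    """Quadratic variance mu + mu^2 / theta."""
    return mu + mu * mu / theta


# --------------------------------------------------------------------------
# design matrix

def build_design(data: pd.DataFrame) -> tuple[np.ndarray, list[str],
                                              np.ndarray, np.ndarray, list]:
    """Treatment-coded design for entries ~ manipulation * group.

    Returns (X, column names, y, participant index, participant ids);
    rows follow the input order.  Reference levels: control_pre, short.
    """
    required = {"participant_id", "group", "manipulation", "entries"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"count dataset missing columns: {sorted(missing)}")
    bad_m = set(data["manipulation"]) - set(MANIPULATION_LEVELS)
    bad_g = set(data["group"]) - set(GROUP_LEVELS)
    if bad_m or bad_g:
        raise ValueError(f"unknown factor levels: {bad_m | bad_g}")
    dup = data.duplicated(subset=["participant_id", "manipulation"])
    if dup.any():
        raise ValueError("duplicate participant x manipulation rows")

    y = data["entries"].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("entries must be nonnegative integers")
    cols: list[np.ndarray] = [np.ones(len(data))]
    names = ["Intercept"]
    m = data["manipulation"].to_numpy()
    g = data["group"].to_numpy()
    for ml in MANIPULATION_LEVELS[1:]:
        cols.append((m == ml).astype(float))
        names.append(f"Manipulation[{_MANIP_LABEL[ml]}]")
    for gl in GROUP_LEVELS[1:]:
        cols.append((g == gl).astype(float))
        names.append(f"Group[{_GROUP_LABEL[gl]}]")
    for ml in MANIPULATION_LEVELS[1:]:
        for gl in GROUP_LEVELS[1:]:
            cols.append(((m == ml) & (g == gl)).astype(float))
            names.append(f"Manipulation[{_MANIP_LABEL[ml]}]:"
                         f"Group[{_GROUP_LABEL[gl]}]")
    X = np.column_stack(cols)
    ids, part_idx = np.unique(data["participant_id"].to_numpy(), return_inverse=True)
    return X, names, y, part_idx, list(ids)


# --------------------------------------------------------------------------
# family log-pmf and derivatives with respect to the linear predictor

def _logpmf_d(y: np.ndarray, log_mu: np.ndarray, family: str, disp: float):
    """log f(y | mu) and its first/second derivatives in eta (mu = e^eta),
    plus the derivative in log(dispersion) for the Fisher-identity score."""
    mu = np.exp(log_mu)
    if family == "poisson":
        logf = y * log_mu - mu - special.gammaln(y + 1.0)
        return logf, y - mu, -mu, None
    if family == "nb2":
        th = disp
        logf = (special.gammaln(y + th) - special.gammaln(th)
                - special.gammaln(y + 1.0)
                + th * np.log(th / (th + mu)) + y * (log_mu - np.log(th + mu)))
        d1 = y - (y + th) * mu / (th + mu)
        d2 = -(y + th) * th * mu / (th + mu) ** 2
        dd = th * (special.digamma(y + th) - special.digamma(th)
                   + np.log(th) - np.log(th + mu) + 1.0
                   - (y + th) / (th + mu))
        return logf, d1, d2, dd
    if family == "nb1":
        a = disp
        r = mu / a
        log1pa = np.log1p(a)
        logf = (special.gammaln(y + r) - special.gammaln(r)
                - special.gammaln(y + 1.0)
                - r * log1pa + y * (np.log(a) - log1pa))
        h = special.digamma(y + r) - special.digamma(r) - log1pa
        d1 = r * h
        d2 = r * h + r * r * (special.polygamma(1, y + r)
                              - special.polygamma(1, r))
        dd = -r * h + y - a * (r + y) / (1.0 + a)
        return logf, d1, d2, dd
    raise ValueError(f"unsupported family {family!r}")


def _olre_obs_logf_d(y: np.ndarray, eta: np.ndarray, sigma_o: float,
                     nodes: tuple[np.ndarray, np.ndarray]):
    """Per-observation Poisson-lognormal probability and derivatives.

    Integrates the observation-level normal intercept u by adaptive
    Gauss-Hermite quadrature; eta-derivatives follow from posterior
    moments of (y - mu e^u) and the log sigma_o derivative from the
    posterior second moment of u.
    """
    z, logw = nodes
    v = sigma_o ** 2
    # Newton for the per-observation mode of -u^2/2v + y(eta+u) - e^(eta+u)
    u = np.zeros_like(eta)
    for _ in range(50):
        mu_u = np.exp(eta + u)
        grad = -u / v + y - mu_u
        hess = -1.0 / v - mu_u
        step = np.clip(-grad / hess, -3.0, 3.0)
        u = u + step
        if np.max(np.abs(step)) < 1e-10:
            break
    sd = 1.0 / np.sqrt(1.0 / v + np.exp(eta + u))
    un = u[..., None] + np.sqrt(2.0) * sd[..., None] * z          # (..., K)
    g = (-0.5 * un**2 / v - 0.5 * np.log(2.0 * np.pi * v)
         + y[..., None] * (eta[..., None] + un) - np.exp(eta[..., None] + un)
         - special.gammaln(y + 1.0)[..., None])
    lt = logw + z**2 + g + np.log(np.sqrt(2.0) * sd)[..., None]
    m = np.max(lt, axis=-1, keepdims=True)
    w_post = np.exp(lt - m)
    logf = np.squeeze(m, -1) + np.log(np.sum(w_post, axis=-1))
    w_post = w_post / np.sum(w_post, axis=-1, keepdims=True)
    mu_nodes = np.exp(eta[..., None] + un)
    s = y[..., None] - mu_nodes
    d1 = np.sum(w_post * s, axis=-1)
    d2 = (np.sum(w_post * (s**2 - mu_nodes), axis=-1) - d1**2)
    dd = np.sum(w_post * un**2, axis=-1) / v - 1.0
    return logf, d1, d2, dd


# --------------------------------------------------------------------------
# marginal likelihood via adaptive Gauss-Hermite quadrature

def _marginal_loglik(y, X, part_idx, n_part, beta, sigma_b, family, disp,
                     n_nodes=15, return_modes=False, return_grad=False):
    """Marginal log-likelihood; optionally its gradient in the packed
    parameter space (beta, log sigma_b[, log dispersion]) through the
    Fisher identity (posterior-expected complete-data score)."""
    z, w = hermgauss(n_nodes)
    logw = np.log(w)
    nodes = (z, logw)
    eta = X @ beta
    vb = sigma_b ** 2

    def obs_terms(b_per_obs):
        if family == "olre":
            return _olre_obs_logf_d(y if b_per_obs.ndim == 1 else y[:, None],
                                    eta[:, None] + b_per_obs
                                    if b_per_obs.ndim == 2 else eta + b_per_obs,
                                    disp, nodes)
        log_mu = (eta[:, None] + b_per_obs if b_per_obs.ndim == 2
                  else eta + b_per_obs)
        yy = y[:, None] if b_per_obs.ndim == 2 else y
        return _logpmf_d(yy, log_mu, family, disp)

    # participant-level mode by damped Newton
    b = np.zeros(n_part)
    for _ in range(60):
        _, d1, d2, _ = obs_terms(b[part_idx])
        grad = np.bincount(part_idx, weights=d1, minlength=n_part) - b / vb
        hess = np.bincount(part_idx, weights=d2, minlength=n_part) - 1.0 / vb
        hess = np.minimum(hess, -1e-8)
        step = np.clip(-grad / hess, -4.0, 4.0)
        b = b + step
        if np.max(np.abs(step)) < 1e-9:
            break
    sd = 1.0 / np.sqrt(-hess)

    bk = b[:, None] + np.sqrt(2.0) * sd[:, None] * z             # (n_part, K)
    logf, d1k, _, ddk = obs_terms(bk[part_idx])                   # (n_obs, K)
    g = np.zeros((n_part, n_nodes))
    np.add.at(g, part_idx, logf)
    g += -0.5 * bk**2 / vb - 0.5 * np.log(2.0 * np.pi * vb)
    lt = logw + z**2 + g + np.log(np.sqrt(2.0) * sd)[:, None]
    ll_i = special.logsumexp(lt, axis=1)
    ll = float(np.sum(ll_i))
    if return_grad:
        w_post = np.exp(lt - ll_i[:, None])                       # (n_part, K)
        w_obs = w_post[part_idx]
        e1 = np.sum(w_obs * d1k, axis=1)                          # E[score_eta]
        grad_beta = X.T @ e1
        grad_lsig = float(np.sum(w_post * (bk**2 / vb - 1.0)))
        pieces = [grad_beta, [grad_lsig]]
        if family != "poisson":
            pieces.append([float(np.sum(w_obs * ddk))])
        grad = np.concatenate([np.atleast_1d(np.asarray(p)) for p in pieces])
        if return_modes:
            return ll, grad, b
        return ll, grad
    if return_modes:
        return ll, b
    return ll


def _poisson_irls(y, X, n_iter=30):
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(np.mean(y), 0.1))
    for _ in range(n_iter):
        mu = np.exp(np.clip(X @ beta, -30, 30))
        W = mu
        z_work = X @ beta + (y - mu) / np.maximum(mu, 1e-8)
        XtW = X.T * W
        try:
            new = np.linalg.solve(XtW @ X, XtW @ z_work)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(new - beta)) < 1e-10:
            beta = new
            break
        beta = new
    return beta


@dataclass
class MixedCountFit:
    """Fitted mixed-effects count regression."""

    family: str
    coef: pd.Series
    se: pd.Series
    cov: np.ndarray                  # fixed-effects covariance block
    sigma_b: float
    dispersion: Optional[float]      # alpha (nb1), theta (nb2), sigma_o (olre)
    loglik: float
    n_obs: int
    n_participants: int
    converged: bool
    fitted_means: np.ndarray         # conditional on EB participant modes
    pearson_residuals: np.ndarray
    resid_df: int
    random_modes: np.ndarray
    params_full: np.ndarray = field(repr=False, default=None)
    cov_full: np.ndarray = field(repr=False, default=None)
    message: str = ""

    @property
    def zvalues(self) -> pd.Series:
        return self.coef / self.se

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues)),
                         index=self.coef.index)

    def summary_table(self) -> pd.DataFrame:
        """Coefficient table in the layout of the study's main analysis."""
        return pd.DataFrame({"log_mean": self.coef, "std_error": self.se,
                             "p": self.pvalues})


def fit_mixed_count(data: pd.DataFrame, family: str = "poisson",
                    n_nodes: int = 15, x0: Optional[np.ndarray] = None,
                    maxiter: int = 200, compute_se: bool = True) -> MixedCountFit:
    """Fit entries ~ manipulation*group + (1|participant) by maximum
    marginal likelihood with adaptive Gauss-Hermite quadrature.

    ``family`` is one of poisson, olre, nb1, nb2.  Standard errors come
    from the observed information (numerical Hessian).  ``x0`` warm-starts
    the optimizer (used heavily by LOOCV).
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    X, names, y, part_idx, ids = build_design(data)
    n_part = len(ids)
    p = X.shape[1]
    has_disp = family != "poisson"

    def unpack(x):
        beta = x[:p]
        sigma_b = np.exp(x[p])
        disp = np.exp(x[p + 1]) if has_disp else None
        return beta, sigma_b, disp

    def nll(x):
        beta, sigma_b, disp = unpack(x)
        ll = _marginal_loglik(y, X, part_idx, n_part, beta, sigma_b,
                              family, disp, n_nodes)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    def nll_grad(x):
        beta, sigma_b, disp = unpack(x)
        ll, grad = _marginal_loglik(y, X, part_idx, n_part, beta, sigma_b,
                                    family, disp, n_nodes, return_grad=True)
        if not np.isfinite(ll) or not np.all(np.isfinite(grad)):
            return 1e12, np.zeros_like(x)
        return -ll, -grad

    if x0 is None:
        beta0 = _poisson_irls(y, X)
        x0 = np.concatenate([beta0, [np.log(0.5)],
                             [0.0] if has_disp else []])
    bounds = ([(None, None)] * p + [(np.log(1e-4), np.log(50.0))]
              + ([(np.log(1e-4), np.log(1e4))] if has_disp else []))
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        res = optimize.minimize(nll_grad, x0, jac=True, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": maxiter, "maxfun": 5000})
    beta, sigma_b, disp = unpack(res.x)
    ll, b_modes = _marginal_loglik(y, X, part_idx, n_part, beta, sigma_b,
                                   family, disp, n_nodes, return_modes=True)

    if compute_se:
        H = _numeric_hessian(nll, res.x)
        cov_full = _safe_inv(H)
    else:
        cov_full = np.full((len(res.x), len(res.x)), np.nan)
    cov_beta = cov_full[:p, :p]
    se = np.sqrt(np.clip(np.diag(cov_beta), 0, None))

    mu_hat = np.exp(X @ beta + b_modes[part_idx])
    var_hat = _family_variance(mu_hat, family, disp)
    pearson = (y - mu_hat) / np.sqrt(var_hat)
    n_var_params = 1 + (1 if has_disp else 0)
    resid_df = len(y) - (p + n_var_params)

    boundary = sigma_b <= 1.5e-4
    msg = res.message if isinstance(res.message, str) else str(res.message)
    if boundary:
        msg += " | random-effect variance at boundary"
    return MixedCountFit(
        family=family, coef=pd.Series(beta, index=names),
        se=pd.Series(se, index=names), cov=cov_beta, sigma_b=float(sigma_b),
        dispersion=None if disp is None else float(disp), loglik=float(ll),
        n_obs=len(y), n_participants=n_part, converged=bool(res.success),
        fitted_means=mu_hat, pearson_residuals=pearson, resid_df=resid_df,
        random_modes=b_modes, params_full=res.x, cov_full=cov_full,
        message=msg)


def _family_variance(mu, family, disp):
    if family in ("poisson", "olre"):
        return mu
    if family == "nb1":
        return mu * (1.0 + disp)
    return mu + mu**2 / disp


def _numeric_hessian(f, x, eps=1e-4):
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / steps[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej)
                    - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * steps[i] * steps[j])
    return H


def _safe_inv(H):
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


# --------------------------------------------------------------------------
# overdispersion diagnostic

def dispersion_ratio(fit: MixedCountFit) -> dict:
    """Pearson overdispersion check: sum of squared Pearson residuals over
    the residual degrees of freedom, with an upper-tail chi-square p."""
    if fit.resid_df <= 0:
        raise ValueError("nonpositive residual degrees of freedom")
    chi2 = float(np.sum(fit.pearson_residuals ** 2))
    return dispersion_ratio_from_chi2(chi2, fit.resid_df)


def dispersion_ratio_from_chi2(pearson_chi2: float, df: int) -> dict:
    if df <= 0:
        raise ValueError("df must be positive")
    ratio = pearson_chi2 / df
    p = float(stats.chi2.sf(pearson_chi2, df))
    return {"ratio": ratio, "pearson_chi2": pearson_chi2, "df": df, "p": p}


# --------------------------------------------------------------------------
# LOOCV model selection

def loocv_select(data: pd.DataFrame,
                 families: Sequence[str] = ("olre", "nb1", "nb2"),
                 granularity: str = "observation",
                 n_nodes: int = 15) -> dict:
    """Leave-one-out cross-validation by mean squared error.

    With ``granularity='observation'`` each observation is held out in
    turn and predicted from a warm-started refit without it, using the
    conditional mean at the participant's re-estimated empirical-Bayes
    mode.  ``granularity='participant'`` drops whole participants and
    predicts from the marginal mean.  The winner has the lowest MSE.
    """
    if granularity not in ("observation", "participant"):
        raise ValueError("granularity must be 'observation' or 'participant'")
    data = data.reset_index(drop=True)
    results: dict[str, dict] = {}
    for family in families:
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        full = fit_mixed_count(data, family, n_nodes=n_nodes, compute_se=False)
        sq_errors, flagged = [], False
        folds = (_obs_folds(data) if granularity == "observation"
                 else _participant_folds(data))
        for train_idx, test_idx in folds:
            train = data.loc[train_idx]
            try:
                refit = fit_mixed_count(train, family, n_nodes=n_nodes,
                                        x0=full.params_full, maxiter=60,
                                        compute_se=False)
            except Exception:
                flagged = True
                break
            pred = _predict_counts(refit, train, data.loc[test_idx])
            sq_errors.extend(
                (data.loc[test_idx, "entries"].to_numpy(dtype=float) - pred) ** 2)
        if flagged:
            results[family] = {"mse": np.inf, "flagged": True}
        else:
            results[family] = {"mse": float(np.mean(sq_errors)),
                               "flagged": False}
    valid = {f: r["mse"] for f, r in results.items() if not r["flagged"]}
    if not valid:
        raise RuntimeError("no family converged on every fold")
    winner = min(valid, key=valid.get)
    return {"per_family": results, "winner": winner}


def _obs_folds(data):
    idx = data.index.to_numpy()
    for i in idx:
        yield idx[idx != i], np.array([i])


def _participant_folds(data):
    for pid in data["participant_id"].unique():
        mask = data["participant_id"] == pid
        yield data.index[~mask].to_numpy(), data.index[mask].to_numpy()


def _predict_counts(fit: MixedCountFit, train: pd.DataFrame,
                    test: pd.DataFrame) -> np.ndarray:
    X, _, _, _, _ = build_design(test)
    eta = X @ fit.coef.to_numpy()
    # build_design orders participants via np.unique; mirror that ordering
    ids_sorted = list(np.unique(train["participant_id"].to_numpy()))
    mode_by_id = dict(zip(ids_sorted, fit.random_modes))
    b = np.array([mode_by_id.get(pid, np.nan)
                  for pid in test["participant_id"]])
    marginal = np.isnan(b)
    b[marginal] = 0.0
    extra = 0.5 * fit.sigma_b**2 * marginal.astype(float)
    if fit.family == "olre":
        extra = extra + 0.5 * fit.dispersion**2
    return np.exp(eta + b + extra)


# --------------------------------------------------------------------------
# interaction and simple-effect tests

def interaction_tests(fit: MixedCountFit) -> dict:
    """Wald tests on the group x manipulation structure.

    Returns the overall 4-df interaction chi-square, per-coefficient
    simple interactions (devaluation and control-post versus control_pre,
    per extensive group), the devaluation simple-interaction contrast
    between the two extensive groups, and the simple group effects on
    the pre-devaluation day (the group main-effect coefficients under
    treatment coding).
    """
    names = list(fit.coef.index)
    inter_idx = [i for i, n in enumerate(names) if ":" in n]
    beta = fit.coef.to_numpy()
    C = fit.cov
    bi = beta[inter_idx]
    Ci = C[np.ix_(inter_idx, inter_idx)]
    W = float(bi @ np.linalg.solve(Ci, bi))
    df = len(inter_idx)
    out = {"interaction_chi2": W, "interaction_df": df,
           "interaction_p": float(stats.chi2.sf(W, df)),
           "simple_interactions": {}, "simple_group_effects": {}}
    for i in inter_idx:
        z = beta[i] / np.sqrt(C[i, i])
        out["simple_interactions"][names[i]] = {
            "estimate": float(beta[i]), "se": float(np.sqrt(C[i, i])),
            "z": float(z), "p": float(2 * stats.norm.sf(abs(z)))}
    # devaluation interaction: extensive vs extensive_parallel
    i1 = names.index("Manipulation[Devaluation]:Group[Extensive]")
    i2 = names.index("Manipulation[Devaluation]:Group[ExtensiveParallel]")
    c = np.zeros(len(beta)); c[i1], c[i2] = 1.0, -1.0
    est = float(c @ beta); var = float(c @ C @ c)
    z = est / np.sqrt(var)
    out["extensive_vs_parallel_devaluation"] = {
        "estimate": est, "se": float(np.sqrt(var)), "z": float(z),
        "p": float(2 * stats.norm.sf(abs(z)))}
    for n in names:
        if n.startswith("Group[") and ":" not in n:
            i = names.index(n)
            z = beta[i] / np.sqrt(C[i, i])
            out["simple_group_effects"][n] = {
                "estimate": float(beta[i]), "se": float(np.sqrt(C[i, i])),
                "z": float(z), "p": float(2 * stats.norm.sf(abs(z)))}
    return out


# --------------------------------------------------------------------------
# finite mixture clustering of the adaptation index

@dataclass
class MixtureFit:
    k: int
    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    loglik: float
    bic: float
    responsibilities: np.ndarray
    degenerate: bool = False


def fit_mixture(values: Sequence[float], k: int, seed: int = 0,
                n_init: int = 20, variance_floor: float = 1e-4,
                tol: float = 1e-8) -> MixtureFit:
    """Univariate Gaussian mixture with k components by multi-start EM.

    Each restart runs EM with the variance floor as a degeneracy guard;
    restarts whose solution pins a component variance at the floor (a
    component collapsing onto tied values — the unbounded-likelihood
    pathology of Gaussian mixtures) are rejected, and the best
    non-degenerate restart wins.  If every restart degenerates, the
    pinned solution is returned flagged ``degenerate``; such a fit has
    no valid maximum-likelihood interpretation and is dropped from BIC
    model selection.  BIC = -2 log L + p log n with p = 3k - 1 free
    parameters.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if len(x) < 10:
        raise ValueError("need at least 10 values for mixture modelling")
    if k < 1:
        raise ValueError("k must be >= 1")
    best, best_ll, fallback, fallback_ll = None, -np.inf, None, -np.inf
    import warnings
    from sklearn.exceptions import ConvergenceWarning
    for i in range(n_init):
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             n_init=1, reg_covar=variance_floor, tol=tol,
                             max_iter=2000, random_state=seed * n_init + i)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gm.fit(x)
        ll = float(gm.score(x) * len(x))
        pinned = bool(np.any(gm.covariances_.reshape(k) <= 2.0 * variance_floor))
        if pinned:
            if ll > fallback_ll:
                fallback, fallback_ll = gm, ll
        elif ll > best_ll:
            best, best_ll = gm, ll
    degenerate = best is None
    gm = best if best is not None else fallback
    ll = best_ll if best is not None else fallback_ll
    order = np.argsort(gm.means_.ravel())
    return MixtureFit(
        k=k, means=gm.means_.ravel()[order],
        variances=gm.covariances_.reshape(k)[order],
        weights=gm.weights_[order],
        loglik=ll, bic=float(gm.bic(x)),
        responsibilities=gm.predict_proba(x)[:, order],
        degenerate=degenerate)


def select_k(values: Sequence[float], ks: Sequence[int] = (1, 2),
             seed: int = 0) -> tuple[int, dict[int, MixtureFit]]:
    """Number of latent subgroups by lowest BIC.

    Degenerate fits (every EM restart collapsed a component) carry no
    valid likelihood and are excluded from the comparison unless every
    candidate k degenerates.
    """
    fits = {k: fit_mixture(values, k, seed=seed) for k in ks}
    valid = {k: f for k, f in fits.items() if not f.degenerate}
    pool = valid or fits
    best = min(pool, key=lambda k: pool[k].bic)
    return best, fits


# --------------------------------------------------------------------------
# rank-based regression (Jaeckel dispersion, Wilcoxon scores)

@dataclass
class RankRegressionFit:
    coef: pd.Series
    intercept: float
    dispersion: float
    tau: float
    n: int
    term_tests: dict
    coef_se: pd.Series
    coef_p: pd.Series
    normalized: bool


def _wilcoxon_scores(n: int) -> np.ndarray:
    i = np.arange(1, n + 1)
    return np.sqrt(12.0) * (i / (n + 1.0) - 0.5)


def _jaeckel_dispersion(resid: np.ndarray) -> float:
    n = len(resid)
    a = _wilcoxon_scores(n)
    return float(np.sum(a * np.sort(resid)))


def _fit_slopes(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Minimize Jaeckel's dispersion over slope coefficients."""
    beta0, *_ = np.linalg.lstsq(
        np.column_stack([np.ones(len(y)), X]), y, rcond=None)
    start = beta0[1:]

    def obj(b):
        return _jaeckel_dispersion(y - X @ b)

    res = optimize.minimize(obj, start, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10,
                                     "maxiter": 20000, "maxfev": 20000})
    return res.x


def _estimate_tau(resid: np.ndarray) -> float:
    """tau = 1 / (sqrt(12) * integral of f^2), f estimated by a Gaussian
    kernel density on the residuals (Silverman bandwidth)."""
    e = np.asarray(resid, dtype=float)
    n = len(e)
    sd = np.std(e, ddof=1)
    iqr = np.subtract(*np.percentile(e, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = max(0.9 * scale * n ** (-0.2), 1e-8)
    d = e[:, None] - e[None, :]
    int_f2 = float(np.mean(stats.norm.pdf(d, scale=np.sqrt(2.0) * h)))
    return 1.0 / (np.sqrt(12.0) * int_f2)


def rank_regression(response: Sequence[float], design: pd.DataFrame,
                    terms: Optional[dict[str, Sequence[str]]] = None,
                    normalize: bool = True) -> RankRegressionFit:
    """Rank-based linear regression with Wilcoxon scores.

    Minimizes Jaeckel's rank dispersion D(beta) = sum a(R(e_i)) e_i over
    the slopes; the intercept is the median residual.  Continuous
    predictors are standardized first (columns that are pure effect codes
    in {-1, +1} are left alone).  ``terms`` maps a term name to the
    design columns it spans; each term gets a drop-in-dispersion F-type
    test F = [(D_reduced - D_full)/q] / (tau/2).
    """
    y = np.asarray(response, dtype=float)
    Xdf = pd.DataFrame(design).astype(float)
    if len(Xdf) != len(y):
        raise ValueError("response and design lengths differ")
    X = Xdf.copy()
    if normalize:
        for c in X.columns:
            vals = set(np.unique(X[c]))
            if vals <= {-1.0, 1.0}:
                continue
            sd = X[c].std(ddof=1)
            if sd == 0:
                raise ValueError(f"constant predictor {c!r}")
            X[c] = (X[c] - X[c].mean()) / sd
    Xm = X.to_numpy()
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise ValueError("design is not full rank")
    n, p = Xm.shape
    slopes = _fit_slopes(y, Xm)
    resid = y - Xm @ slopes
    intercept = float(np.median(resid))
    D_full = _jaeckel_dispersion(resid)
    tau = _estimate_tau(resid)

    Xc = Xm - Xm.mean(axis=0)
    cov = tau**2 * _safe_inv(Xc.T @ Xc)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    zs = slopes / se
    pvals = 2 * stats.norm.sf(np.abs(zs))

    term_tests = {}
    terms = terms or {c: [c] for c in X.columns}
    for name, cols in terms.items():
        keep = [c for c in X.columns if c not in cols]
        q = len(cols)
        if keep:
            reduced = _fit_slopes(y, X[keep].to_numpy())
            D_red = _jaeckel_dispersion(y - X[keep].to_numpy() @ reduced)
        else:
            D_red = _jaeckel_dispersion(y - np.median(y))
        F = max((D_red - D_full) / q, 0.0) / (tau / 2.0)
        term_tests[name] = {
            "F": float(F), "df1": q, "df2": n - p - 1,
            "p": float(stats.f.sf(F, q, n - p - 1)),
            "drop_in_dispersion": float(D_red - D_full)}
    return RankRegressionFit(
        coef=pd.Series(slopes, index=X.columns), intercept=intercept,
        dispersion=D_full, tau=float(tau), n=n, term_tests=term_tests,
        coef_se=pd.Series(se, index=X.columns),
        coef_p=pd.Series(pvals, index=X.columns), normalized=normalize)
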