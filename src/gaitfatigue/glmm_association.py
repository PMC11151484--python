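"""Per-feature binomial mixed models of fatigue scores.

Each digital gait measure is screened with its own generalised linear
mixed model: the 0-6 Likert score is treated as y successes out of 6
trials with a logit link, a fixed intercept and slope for the
(standardised) feature, and a Gaussian random intercept per subject,

    logit E(Y_ij / 6) = b0 + b1 * x_ij + a_i,   a_i ~ N(0, sigma^2).

The marginal likelihood integrates the random intercept with adaptive
Gauss-Hermite quadrature (default 10 nodes, re-centred at each subject's
conditional mode).  Observations are weighted by the inverse frequency of
their score so under-represented scores are not swamped; the raw inverse
counts satisfy sum(w * count) = n and are rescaled to mean 1 before
entering the likelihood so that estimation and inference keep the
ordinary scale.  The Wald p-value for the slope uses a subject-clustered
sandwich covariance, which is invariant to the overall weight scale.

Goodness of fit is summarised by the marginal and conditional R² of
Nakagawa & Schielzeth: with sigma2_f the variance of the fixed-effect
linear predictor and pi^2/3 the logit distribution-specific variance,

    R2_marginal    = sigma2_f / (sigma2_f + sigma2_a + pi^2/3)
    R2_conditional = (sigma2_f + sigma2_a) / (same denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit, gammaln, log_expit
from scipy.stats import norm

N_TRIALS = 6
LOGIT_RESIDUAL_VAR = np.pi ** 2 / 3.0


@dataclass
class GLMMResult:
    feature: str
    beta: float
    se: float
    p_value: float
    intercept: float
    sigma_subject: float
    r2_marginal: float
    r2_conditional: float
    converged: bool
    n_obs: int
    n_subjects: int


def inverse_frequency_weights(scores) -> np.ndarray:
    """Raw inverse score-frequency weights: w_i = 1 / count(score_i).

    These satisfy the identity sum_i w_i * count(score_i) = n.
    """
    s = np.asarray(scores)
    _, inv, counts = np.unique(s, return_inverse=True, return_counts=True)
    return 1.0 / counts[inv]


class _AGQModel:
    """Weighted binomial random-intercept likelihood with AGQ."""

    def __init__(self, y, x, subject_idx, weights, n_quad=10, n_trials=N_TRIALS):
        self.y = np.asarray(y, dtype=float)
        self.x = np.asarray(x, dtype=float)
        self.idx = np.asarray(subject_idx)
        self.w = np.asarray(weights, dtype=float)
        self.m = int(self.idx.max()) + 1
        self.n_trials = n_trials
        self.nodes, self.gh_w = hermgauss(n_quad)
        self.const = float(np.sum(self.w * (
            gammaln(n_trials + 1) - gammaln(self.y + 1)
            - gammaln(n_trials - self.y + 1))))

    def _sums(self, values):
        return np.bincount(self.idx, weights=values, minlength=self.m)

    def _conditional_mode(self, eta, sigma2):
        """Vectorised Newton solve for each subject's posterior mode."""
        a = np.zeros(self.m)
        for _ in range(50):
            la = eta + a[self.idx]
            p = expit(la)
            grad = self._sums(self.w * (self.y - self.n_trials * p)) - a / sigma2
            hess = -self._sums(self.w * self.n_trials * p * (1 - p)) - 1.0 / sigma2
            step = grad / hess
            a -= np.clip(step, -5, 5)
            if np.abs(step).max() < 1e-10:
                break
        return a, -hess

    def loglik_by_subject(self, params) -> np.ndarray:
        b0, b1, log_sigma = params
        sigma = np.exp(log_sigma)
        sigma2 = sigma ** 2
        eta = b0 + b1 * self.x
        a_hat, neg_h = self._conditional_mode(eta, sigma2)
        tau = 1.0 / np.sqrt(neg_h)
        # sum over nodes of exp(z^2 + f(a_hat + sqrt(2) tau z)) * gh_w
        vals = np.empty((len(self.nodes), self.m))
        for q, (z, wq) in enumerate(zip(self.nodes, self.gh_w)):
            a = a_hat + np.sqrt(2.0) * tau * z
            la = eta + a[self.idx]
            ll = self.w * (self.y * log_expit(la)
                           + (self.n_trials - self.y) * log_expit(-la))
            f = self._sums(ll) - a ** 2 / (2 * sigma2)
            vals[q] = np.log(wq) + z ** 2 + f
        peak = vals.max(axis=0)
        integral = peak + np.log(np.exp(vals - peak).sum(axis=0))
        return (integral + np.log(np.sqrt(2.0) * tau)
                - np.log(sigma * np.sqrt(2 * np.pi)))

    def negloglik(self, params) -> float:
        return -(self.loglik_by_subject(params).sum() + self.const)


def _numdiff_hessian(fun, x, eps=1e-4):
    k = len(x)
    h = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            pp = x.copy(); pp[i] += eps; pp[j] += eps
            pm = x.copy(); pm[i] += eps; pm[j] -= eps
            mp = x.copy(); mp[i] -= eps; mp[j] += eps
            mm = x.copy(); mm[i] -= eps; mm[j] -= eps
            h[i, j] = h[j, i] = (fun(pp) - fun(pm) - fun(mp) + fun(mm)) / (4 * eps ** 2)
    return h


def _cluster_jacobian(fun_vec, x, eps=1e-5):
    cols = []
    for i in range(len(x)):
        xp = x.copy(); xp[i] += eps
        xm = x.copy(); xm[i] -= eps
        cols.append((fun_vec(xp) - fun_vec(xm)) / (2 * eps))
    return np.column_stack(cols)


def fit_glmm(
    feature_values,
    scores,
    subject_ids,
    weights=None,
    feature: str = "feature",
    n_quad: int = 10,
    normalize_weights: bool = True,
    standardize: bool = True,
) -> GLMMResult:
    """Fit the weighted binomial random-intercept model for one feature.

    Rows with a missing feature value or score are dropped.  ``weights``
    defaults to inverse score-frequency weights computed on the retained
    rows; ``normalize_weights`` rescales them to mean 1 (see module notes).
    Features are standardised by default, so ``beta`` is per SD of the
    feature.  A constant feature, fewer than two subjects, or optimiser
    failure yield ``converged=False`` with NaN R².
    """
    df = pd.DataFrame({
        "x": np.asarray(feature_values, dtype=float),
        "y": np.asarray(scores, dtype=float),
        "s": np.asarray(subject_ids),
    })
    if weights is not None:
        df["w"] = np.asarray(weights, dtype=float)
    df = df.dropna(subset=["x", "y"])
    n_obs = len(df)
    subjects, idx = np.unique(df["s"].to_numpy(), return_inverse=True)
    m = len(subjects)
    failed = GLMMResult(feature, np.nan, np.nan, np.nan, np.nan, np.nan,
                        np.nan, np.nan, False, n_obs, m)
    if n_obs < 4 or m < 2:
        return failed
    x = df["x"].to_numpy()
    if standardize:
        sd = x.std()
        if sd == 0 or not np.isfinite(sd):
            return failed
        x = (x - x.mean()) / sd
    elif x.std() == 0:
        return failed
    y = df["y"].to_numpy()
    if "w" in df:
        w = df["w"].to_numpy()
    else:
        w = inverse_frequency_weights(y)
    if normalize_weights:
        w = w / w.mean()

    model = _AGQModel(y, x, idx, w, n_quad=n_quad)
    p_bar = np.clip(y.mean() / N_TRIALS, 0.05, 0.95)
    start = np.array([np.log(p_bar / (1 - p_bar)), 0.0, np.log(0.5)])
    res = optimize.minimize(
        model.negloglik, start, method="L-BFGS-B",
        bounds=[(-8, 8), (-8, 8), (-6, 2)],
    )
    if not res.success or not np.isfinite(res.fun):
        return failed
    b0, b1, log_sigma = res.x
    sigma = float(np.exp(log_sigma))

    hess = _numdiff_hessian(model.negloglik, res.x)
    try:
        a_inv = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return failed
    grads = _cluster_jacobian(model.loglik_by_subject, res.x)
    bread = a_inv @ (grads.T @ grads) @ a_inv * (m / max(m - 1, 1))
    se = float(np.sqrt(max(bread[1, 1], 0.0)))
    if not np.isfinite(se) or se == 0:
        return failed
    z = b1 / se
    p = float(2 * norm.sf(abs(z)))

    r2m, r2c = r2_nakagawa(b1, x, sigma)
    return GLMMResult(feature, float(b1), se, p, float(b0), sigma,
                      r2m, r2c, True, n_obs, m)


def r2_nakagawa(beta, x, sigma_subject) -> tuple[float, float]:
    """Marginal and conditional R² on the logit latent scale.

    The fixed-effect variance is the variance of beta * x over the
    observations; the distribution-specific residual variance for the
    binomial-logit family is pi^2/3.  Zero total variance yields (0, 0).
    """
    var_f = float(np.var(np.asarray(beta) * np.asarray(x)))
    var_a = float(sigma_subject) ** 2
    denom = var_f + var_a + LOGIT_RESIDUAL_VAR
    if denom == 0:
        return 0.0, 0.0
    return var_f / denom, (var_f + var_a) / denom


def associate(dataset: pd.DataFrame, features: list[str], label: str = "pf_score",
              n_quad: int = 10) -> pd.DataFrame:
    """Fit one GLMM per feature column against a fatigue label.

    Returns one row per feature with the coefficient, p-value and both R²;
    feature names of the form domain__group__measure__statistic are split
    into their parts for ranking.
    """
    rows = []
    for col in features:
        res = fit_glmm(dataset[col], dataset[label], dataset["subject_id"],
                       feature=col, n_quad=n_quad)
        parts = col.split("__")
        rows.append({
            "feature": col,
            "domain": parts[0] if len(parts) > 2 else "",
            "group": parts[1] if len(parts) > 2 else "",
            "statistic": parts[-1],
            "label": label,
            "beta": res.beta,
            "p_value": res.p_value,
            "r2_marginal": res.r2_marginal,
            "r2_conditional": res.r2_conditional,
            "converged": res.converged,
            "n_obs": res.n_obs,
            "n_subjects": res.n_subjects,
        })
    return pd.DataFrame(rows)


def rank_features(results: pd.DataFrame, by: str = "r2_conditional",
                  key: str = "group", alpha: float = 0.05) -> pd.DataFrame:
    """Rank feature groups (or statistics) by double-weighted mean R².

    Each entry's R² enters the group mean once, twice when its association
    is statistically significant (p < alpha).  Symmetric use with
    ``key="statistic"`` ranks the pooled statistics across groups.
    """
    df = results[results["converged"]].copy()
    df["weight"] = np.where(df["p_value"] < alpha, 2.0, 1.0)
    df["wr2"] = df["weight"] * df[by]
    grouped = df.groupby(key).apply(
        lambda g: g["wr2"].sum() / g["weight"].sum(), include_groups=False)
    out = grouped.sort_values(ascending=False).rename("mean_r2").reset_index()
    out["rank"] = np.arange(1, len(out) + 1)
    return out
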