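"""Negative-binomial GAM for stable population sizes.

The response is the stable population size extracted from each training
time series; the linear predictor is a sum of low-rank smooths of mean EVI,
proportion of area within 12 km of water, and PIKE, with ln(area) as an
offset so the model is equivalently one of density. Each smooth uses a
rank-3 thin-plate regression spline basis (an unpenalized linear part plus
one penalized eigen-component of the cubic radial penalty), which caps every
term at three knots and so guards against overfitting an 18-point training
set. Smoothing parameters minimize GCV; the NB dispersion theta
(variance = mu + mu^2/theta) is estimated by outer maximum likelihood.

Candidate formulas — null, EVI + water, EVI + water + PIKE — are compared by
AICc with effective degrees of freedom as the parameter count, plus
leave-one-out cross-validation metrics (cvCOR, Willmott's D, mean bias
error) and hat/Cook influence diagnostics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln
from scipy.stats import pearsonr

logger = logging.getLogger(__name__)

FORMULAS = {
    "null": [],
    "evi_water": ["evi", "prop_12_water"],
    "evi_water_pike": ["evi", "prop_12_water", "pike"],
}

_BASIS_DIM = 3  # knots per smooth: linear null space + 1 penalized component


# ---------------------------------------------------------------------------
# rank-3 thin-plate regression spline basis (1-D, m = 2)

@dataclass
class TprsSmooth:
    """Low-rank 1-D thin-plate spline basis for one covariate.

    The full thin-plate penalty matrix E_ij = |x_i - x_j|^3 is projected
    orthogonal to the null space {1, x} and eigendecomposed; the leading
    k - 2 eigenvectors give the penalized basis columns, with the
    eigenvalues as their penalty. Columns are centred (sum-to-zero over the
    training points) for identifiability with the global intercept and
    scaled to unit SD for conditioning.
    """

    name: str
    knots: np.ndarray
    delta: np.ndarray          # (n_knots, k-2) representer coefficients
    x_mean: float
    x_scale: float
    col_means: np.ndarray      # means of the penalized columns (pre-centering)
    col_scales: np.ndarray
    penalty: np.ndarray        # diagonal of S for [linear, penalized...] coefs

    @classmethod
    def build(cls, name: str, x: np.ndarray, k: int = _BASIS_DIM) -> "TprsSmooth":
        x = np.asarray(x, dtype=float)
        knots = np.unique(x)
        n = len(knots)
        if n < k:
            raise ValueError(f"smooth {name!r}: need >= {k} distinct covariate values")
        E = np.abs(knots[:, None] - knots[None, :]) ** 3
        T = np.column_stack([np.ones(n), knots])
        Q, _ = np.linalg.qr(T)
        P = np.eye(n) - Q @ Q.T
        Et = P @ E @ P
        vals, vecs = np.linalg.eigh(Et)
        order = np.argsort(np.abs(vals))[::-1][: k - 2]
        delta = P @ vecs[:, order]                    # representer coefficients
        pen = np.abs(vals[order])                     # delta_j' E delta_j

        raw = E @ delta                               # basis at the knots
        col_means = raw.mean(axis=0)
        col_scales = raw.std(axis=0)
        col_scales[col_scales == 0] = 1.0
        x_scale = x.std() or 1.0
        # rescaling a column by 1/s rescales its coefficient by s, hence the
        # penalty on the new coefficient by 1/s^2
        penalty = np.concatenate([[0.0], pen / col_scales**2])
        return cls(name=name, knots=knots, delta=delta, x_mean=float(x.mean()),
                   x_scale=float(x_scale), col_means=col_means,
                   col_scales=col_scales, penalty=penalty)

    @property
    def n_cols(self) -> int:
        return 1 + self.delta.shape[1]

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lin = (x - self.x_mean) / self.x_scale
        raw = (np.abs(x[:, None] - self.knots[None, :]) ** 3) @ self.delta
        pen = (raw - self.col_means) / self.col_scales
        return np.column_stack([lin, pen])


# ---------------------------------------------------------------------------
# NB likelihood pieces

def _nb_loglik(y, mu, theta):
    return float(np.sum(gammaln(y + theta) - gammaln(theta) - gammaln(y + 1.0)
                        + theta * np.log(theta) + y * np.log(mu)
                        - (y + theta) * np.log(mu + theta)))


def _nb_deviance(y, mu, theta):
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y + theta) * np.log((y + theta) / (mu + theta))))


# ---------------------------------------------------------------------------
# fitted-model container

@dataclass
class GamFit:
    formula_id: str
    terms: list
    smooths: list              # list of TprsSmooth
    beta: np.ndarray
    Vp: np.ndarray             # posterior covariance of beta (scale 1)
    lambdas: np.ndarray        # one smoothing parameter per smooth
    theta: float               # NB dispersion (variance = mu + mu^2/theta)
    edf: float
    hat: np.ndarray
    weights: np.ndarray        # final PIRLS working weights
    fitted: np.ndarray         # fitted stable sizes (response scale)
    y: np.ndarray
    offset: np.ndarray
    deviance: float
    null_deviance: float
    loglik: float
    aicc: float
    deviance_explained: float
    r2: float
    r2_adj: float
    cor: float
    gcv: float
    training_ranges: dict = field(default_factory=dict)

    def design(self, data: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(data))]
        for sm_, term in zip(self.smooths, self.terms):
            cols.append(sm_.transform(data[term].to_numpy(dtype=float)))
        return np.column_stack(cols) if cols else np.ones((len(data), 1))

    def predict_size(self, data: pd.DataFrame, log_area: np.ndarray,
                     beta: np.ndarray | None = None) -> np.ndarray:
        """Predicted stable size(s); `beta` may be a (p,) or (m, p) array."""
        X = self.design(data)
        b = self.beta if beta is None else np.asarray(beta)
        eta = X @ (b.T if b.ndim == 2 else b)
        if b.ndim == 2:
            return np.exp(eta + np.asarray(log_area)[:, None]).T
        return np.exp(eta + np.asarray(log_area))

    def extrapolation_flags(self, data: pd.DataFrame) -> np.ndarray:
        flags = np.zeros(len(data), dtype=bool)
        for term, (lo, hi) in self.training_ranges.items():
            v = data[term].to_numpy(dtype=float)
            flags |= (v < lo) | (v > hi)
        return flags


@dataclass
class GamDiagnostics:
    hat: np.ndarray
    cook: np.ndarray
    high_leverage: np.ndarray  # hat > 3 * mean(hat)
    influential: np.ndarray    # cook > 1


# ---------------------------------------------------------------------------
# core PIRLS

def _assemble_penalty(smooths, lambdas, p):
    S = np.zeros((p, p))
    j = 1
    for sm_, lam in zip(smooths, lambdas):
        d = sm_.n_cols
        S[j:j + d, j:j + d] += lam * np.diag(sm_.penalty)
        j += d
    return S

def _pirls(X, y, offset, theta, S, beta0=None, max_iter=60, tol=1e-9):
    n, p = X.shape
    if beta0 is None:
        mu = np.maximum(y, 0.5)
        eta = np.log(mu) - offset
        # one least-squares step to get a starting beta
        beta = np.linalg.lstsq(X, eta, rcond=None)[0]
    else:
        beta = beta0.copy()
    eta = X @ beta
    mu = np.exp(np.clip(eta + offset, -30, 30))
    dev = _nb_deviance(y, mu, theta)
    for _ in range(max_iter):
        w = mu / (1.0 + mu / theta)
        z = eta + (y - mu) / mu
        WX = w[:, None] * X
        H = X.T @ WX + S
        try:
            beta_new = np.linalg.solve(H, WX.T @ z)
        except np.linalg.LinAlgError:  # rank-deficient design
            beta_new = np.linalg.lstsq(H, WX.T @ z, rcond=None)[0]
        # step halving if the fit worsened appreciably
        step, accepted = 1.0, None
        while step >= 1e-3:
            beta_try = beta + step * (beta_new - beta)
            eta_try = X @ beta_try
            mu_try = np.exp(np.clip(eta_try + offset, -30, 30))
            dev_try = _nb_deviance(y, mu_try, theta)
            if np.isfinite(dev_try) and dev_try <= dev + 1e-7 * (abs(dev) + 1.0):
                accepted = (beta_try, eta_try, mu_try, dev_try)
                break
            step /= 2.0
        if accepted is None:
            break
        beta, eta, mu, dev_new = accepted
        converged = abs(dev - dev_new) < tol * (abs(dev_new) + 0.1)
        dev = dev_new
        if converged:
            break
    w = mu / (1.0 + mu / theta)
    WX = w[:, None] * X
    H = X.T @ WX + S
    try:
        Hinv = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        Hinv = np.linalg.pinv(H)
    edf = float(np.trace(Hinv @ (X.T @ WX)))
    hat = np.einsum("ij,jk,ik->i", X, Hinv, X) * w
    return beta, mu, dev, edf, hat, Hinv, w


def _estimate_theta(y, mu, lo=0.05, hi=1e5):
    def nll(log_th):
        return -_nb_loglik(y, mu, math.exp(log_th))
    res = optimize.minimize_scalar(nll, bounds=(math.log(lo), math.log(hi)),
                                   method="bounded",
                                   options={"xatol": 1e-3})
    return float(math.exp(res.x))


def fit_gam(
    training: pd.DataFrame,
    formula_id: str = "evi_water_pike",
    response: str = "stable_size",
    offset_col: str = "log_area",
    theta: float | None = None,
    lambda0: np.ndarray | None = None,
    gcv_maxiter: int = 120,
    theta_iter: int = 4,
) -> GamFit:
    """Fit one candidate NB GAM.

    Stable sizes are rounded to the nearest integer (NB support) before
    fitting. Smoothing parameters minimize GCV = n D / (n - edf)^2 via
    Nelder-Mead on log-lambda, warm-startable through `lambda0`; theta is
    re-estimated by ML after each GCV optimization (`theta` fixes it
    instead, as during Monte Carlo refits where speed matters).
    """
    if formula_id not in FORMULAS:
        raise ValueError(f"unknown formula_id {formula_id!r}")
    terms = FORMULAS[formula_id]
    n = len(training)
    if n < 6:
        raise ValueError("need at least 6 training rows")
    y = np.round(training[response].to_numpy(dtype=float))
    if np.any(y < 0) or np.any(~np.isfinite(y)):
        raise ValueError("responses must be finite and non-negative")
    if np.all(y == 0):
        raise ValueError("all responses are zero")
    offset = training[offset_col].to_numpy(dtype=float)

    smooths = [TprsSmooth.build(t, training[t].to_numpy(dtype=float)) for t in terms]
    p = 1 + sum(s.n_cols for s in smooths)
    X = np.column_stack([np.ones(n)] + [s.transform(training[t].to_numpy(dtype=float))
                                        for s, t in zip(smooths, terms)])

    th = theta if theta is not None else 10.0
    log_lam = (np.log(lambda0) if lambda0 is not None and len(smooths)
               else np.zeros(len(smooths)))
    state = {"beta": None}

    def gcv_of(log_lam_vec, th_):
        S = _assemble_penalty(smooths, np.exp(log_lam_vec), p)
        beta, mu, dev, edf, *_ = _pirls(X, y, offset, th_, S, beta0=state["beta"])
        state["beta"] = beta
        denom = max(n - edf, 1e-3)
        return n * dev / denom**2

    for _ in range(max(theta_iter, 1)):
        if len(smooths):
            # explicit simplex: log-lambda needs order-of-magnitude steps
            simplex = np.vstack([log_lam] +
                                [log_lam + 3.0 * np.eye(len(log_lam))[i]
                                 for i in range(len(log_lam))])
            res = optimize.minimize(gcv_of, log_lam, args=(th,),
                                    method="Nelder-Mead",
                                    options={"maxiter": gcv_maxiter,
                                             "initial_simplex": simplex,
                                             "xatol": 1e-2, "fatol": 1e-4})
            log_lam = res.x
        S = _assemble_penalty(smooths, np.exp(log_lam), p)
        beta, mu, dev, edf, hat, Hinv, w = _pirls(X, y, offset, th, S,
                                                  beta0=state["beta"])
        if theta is not None:
            break
        th_new = _estimate_theta(y, mu)
        if abs(math.log(th_new) - math.log(th)) < 1e-3:
            th = th_new
            break
        th = th_new
    S = _assemble_penalty(smooths, np.exp(log_lam), p)
    beta, mu, dev, edf, hat, Hinv, w = _pirls(X, y, offset, th, S,
                                              beta0=state["beta"])

    # null deviance: intercept-only NB fit with the same offset and theta
    X0 = np.ones((n, 1))
    _, mu0, null_dev, *_ = _pirls(X0, y, offset, th, np.zeros((1, 1)))

    ll = _nb_loglik(y, mu, th)
    k = edf + 1.0  # + dispersion
    aicc_val = -2.0 * ll + 2 * k
    if n - k - 1 > 0:
        aicc_val += 2 * k * (k + 1) / (n - k - 1)
    else:
        aicc_val = math.inf

    if np.std(mu) > 0 and np.std(y) > 0:
        cor = float(pearsonr(y, mu)[0])
    else:
        cor = 0.0
    r2 = cor**2
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / max(n - edf - 1, 1e-3)
    gcv = n * dev / max(n - edf, 1e-3)**2

    ranges = {t: (float(training[t].min()), float(training[t].max())) for t in terms}
    return GamFit(formula_id=formula_id, terms=terms, smooths=smooths,
                  beta=beta, Vp=Hinv, lambdas=np.exp(log_lam), theta=th,
                  edf=edf, hat=hat, weights=w, fitted=mu, y=y, offset=offset,
                  deviance=dev, null_deviance=null_dev, loglik=ll,
                  aicc=aicc_val,
                  deviance_explained=1.0 - dev / null_dev if null_dev > 0 else np.nan,
                  r2=r2, r2_adj=r2_adj, cor=cor, gcv=gcv,
                  training_ranges=ranges)


# ---------------------------------------------------------------------------
# metrics and model comparison

def willmott_d(obs: np.ndarray, pred: np.ndarray) -> float:
    """Willmott's index of agreement D in [0, 1]; 1 = perfect prediction."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    obar = obs.mean()
    denom = np.sum((np.abs(pred - obar) + np.abs(obs - obar)) ** 2)
    if denom == 0:
        return 1.0
    return float(1.0 - np.sum((pred - obs) ** 2) / denom)


def mean_bias_error(obs: np.ndarray, pred: np.ndarray) -> float:
    return float(np.mean(np.asarray(pred, float) - np.asarray(obs, float)))


def loocv_metrics(training: pd.DataFrame, formula_id: str,
                  **fit_kwargs) -> tuple[float, float, float]:
    """Leave-one-out CV on the response (size) scale.

    Refits the candidate excluding each row in turn and predicts it; returns
    (cvCOR, Willmott's D, MBE) over the held-out predictions. Folds whose
    refit fails are dropped and logged.
    """
    obs, pred = [], []
    for i in range(len(training)):
        sub = training.drop(training.index[i])
        row = training.iloc[[i]]
        try:
            f = fit_gam(sub, formula_id=formula_id, **fit_kwargs)
        except Exception as exc:
            logger.warning("LOOCV fold %d failed for %s: %s", i, formula_id, exc)
            continue
        p = f.predict_size(row, row["log_area"].to_numpy(dtype=float))[0]
        obs.append(float(np.round(row["stable_size"].iloc[0])))
        pred.append(float(p))
    obs, pred = np.asarray(obs), np.asarray(pred)
    if len(obs) < 3:
        raise RuntimeError("too few successful LOOCV folds")
    cvcor = float(pearsonr(obs, pred)[0]) if np.std(pred) > 0 else 0.0
    return cvcor, willmott_d(obs, pred), mean_bias_error(obs, pred)


def select_gam(training: pd.DataFrame, formulas=("null", "evi_water",
                                                 "evi_water_pike"),
               **fit_kwargs) -> tuple[pd.DataFrame, dict]:
    """AICc comparison of the candidate formulas with LOOCV metrics.

    Returns (selection table, dict of fitted candidates). Failed candidates
    are marked inadmissible; AICc weights are computed over the admissible
    set.
    """
    fits, rows = {}, []
    for fid in formulas:
        try:
            fit = fit_gam(training, formula_id=fid, **fit_kwargs)
            cvcor, d, mbe = loocv_metrics(training, fid, **fit_kwargs)
        except Exception as exc:
            logger.warning("GAM candidate %s inadmissible: %s", fid, exc)
            rows.append({"formula_id": fid, "aicc": np.inf, "admissible": False})
            continue
        fits[fid] = fit
        rows.append({"formula_id": fid, "aicc": fit.aicc,
                     "r2": fit.r2, "r2_adj": fit.r2_adj, "cor": fit.cor,
                     "deviance_explained": fit.deviance_explained,
                     "edf": fit.edf, "theta": fit.theta,
                     "cvcor": cvcor, "willmott_d": d, "mbe": mbe,
                     "admissible": True})
    table = pd.DataFrame(rows)
    if not table["admissible"].any():
        raise RuntimeError("no admissible GAM candidate")
    amin = table.loc[table["admissible"], "aicc"].min()
    table["delta_aicc"] = table["aicc"] - amin
    rel = np.where(table["admissible"], np.exp(-0.5 * table["delta_aicc"]), 0.0)
    table["weight"] = rel / rel.sum()
    table["selected"] = table["aicc"] == amin
    return table, fits


# ---------------------------------------------------------------------------
# diagnostics

def diagnostics(fit: GamFit) -> GamDiagnostics:
    """Hat values and Cook's distances for every training row.

    Cook's distance uses the standard GLM form with the effective degrees of
    freedom as the parameter count:
    D_i = r_{P,i}^2 h_i / (edf (1 - h_i)^2), NB variance mu + mu^2/theta.
    """
    v = fit.fitted + fit.fitted**2 / fit.theta
    r_p = (fit.y - fit.fitted) / np.sqrt(v)
    h = np.clip(fit.hat, 0.0, 1.0 - 1e-10)
    cook = r_p**2 * h / (max(fit.edf, 1e-6) * (1.0 - h) ** 2)
    return GamDiagnostics(hat=fit.hat, cook=cook,
                          high_leverage=fit.hat > 3.0 * fit.hat.mean(),
                          influential=cook > 1.0)


def sensitivity_refit(training: pd.DataFrame, drop_row, formula_id:
                      str = "evi_water_pike", predict_on: pd.DataFrame | None = None,
                      **fit_kwargs) -> dict:
    """Impact of excluding one training row.

    Refits with and without the row and compares predictions over
    `predict_on` (default: the remaining training rows, which lie inside the
    reduced covariate range). Returns both fits and the Pearson correlation
    of their predictions.
    """
    full = fit_gam(training, formula_id=formula_id, **fit_kwargs)
    reduced_data = training.drop(index=drop_row)
    reduced = fit_gam(reduced_data, formula_id=formula_id, **fit_kwargs)
    target = reduced_data if predict_on is None else predict_on
    la = target["log_area"].to_numpy(dtype=float)
    p_full = full.predict_size(target, la)
    p_red = reduced.predict_size(target, la)
    if np.std(p_full) > 0 and np.std(p_red) > 0:
        corr = float(pearsonr(p_full, p_red)[0])
    else:
        corr = 1.0 if np.allclose(p_full, p_red) else 0.0
    return {"full": full, "reduced": reduced, "correlation": corr,
            "pred_full": p_full, "pred_reduced": p_red}
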