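"""Poaching-intensity (PIKE) estimation and prediction.

PIKE — the proportion of illegally killed elephants — is the ratio of illegal
to total carcasses found at a monitored site. Carcass counts are amalgamated
over the monitoring window (2002-2014 by default) to damp stochastic
variability, sites with fewer than 20 amalgamated carcasses are excluded, and
a set of candidate quasi-binomial GLMs (logit link, weighted by total
carcasses) relates PIKE to site covariates. Candidates are compared by QAICc
computed with the global model's dispersion and combined into a single
predictive average model; unmonitored protected areas receive a modeled PIKE
with an SE on the linear-predictor (logit) scale for downstream Monte Carlo
propagation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

logger = logging.getLogger(__name__)


@dataclass
class PikeEstimate:
    site_id: str
    pike: float
    eta: float
    eta_se: float
    source: str                # "empirical" | "modeled"
    carcasses_total: int = 0


@dataclass
class PikeGlm:
    """Candidate quasi-binomial fits and their QAICc average."""

    covariates: list                     # full covariate pool, fixed column order
    candidates: list                     # list of dicts: terms, params, cov, qaicc, weight
    dispersion: float                    # global-model Pearson dispersion
    avg_params: pd.Series                # averaged coefficients (zeros for absent terms)

    def design_row(self, covariates: pd.Series | dict) -> np.ndarray:
        x = [1.0]
        for c in self.covariates:
            if c not in covariates or pd.isna(covariates[c]):
                raise ValueError(f"missing covariate {c!r} for PIKE prediction")
            x.append(float(covariates[c]))
        return np.asarray(x)


def amalgamate_carcasses(records: pd.DataFrame, years=(2002, 2014)) -> pd.DataFrame:
    """Sum illegal and total carcasses per site within the monitoring window."""
    req = {"site_id", "year", "illegal_carcasses", "total_carcasses"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"carcass records missing columns {sorted(missing)}")
    if (records["illegal_carcasses"] > records["total_carcasses"]).any():
        bad = records.index[records["illegal_carcasses"] > records["total_carcasses"]]
        raise ValueError(f"illegal > total carcasses at rows {list(bad[:5])}")
    lo, hi = years
    w = records[(records["year"] >= lo) & (records["year"] <= hi)]
    out = (w.groupby("site_id", sort=True)[["illegal_carcasses", "total_carcasses"]]
           .sum().reset_index())
    return out


def filter_low_carcass_sites(totals: pd.DataFrame, min_total: int = 20) -> pd.DataFrame:
    """Retain sites whose amalgamated carcass count is at least min_total."""
    keep = totals[totals["total_carcasses"] >= min_total].reset_index(drop=True)
    n_drop = len(totals) - len(keep)
    if n_drop:
        logger.info("excluded %d site(s) with < %d amalgamated carcasses",
                    n_drop, min_total)
    if keep.empty:
        logger.warning("all sites fell below the %d-carcass threshold", min_total)
    return keep


def empirical_pike(illegal: int, total: int, site_id: str = "") -> PikeEstimate:
    """Empirical PIKE = illegal / total, with a binomial logit-scale SE.

    The SE is carried for optional propagation; boundary proportions (0 or 1)
    get eta at a continuity-corrected value and their SE from the corrected
    count, since the raw logit is infinite there.
    """
    if total <= 0:
        raise ValueError("total carcasses must be > 0 for empirical PIKE")
    if illegal < 0 or illegal > total:
        raise ValueError("need 0 <= illegal <= total")
    p = illegal / total
    # Anscombe-style continuity correction for the logit and its SE
    pc = (illegal + 0.5) / (total + 1.0)
    eta = float(logit(pc))
    eta_se = float(np.sqrt(1.0 / (total * pc * (1.0 - pc))))
    return PikeEstimate(site_id=site_id, pike=float(p), eta=eta, eta_se=eta_se,
                        source="empirical", carcasses_total=int(total))


def default_candidate_sets(covariates: list[str]) -> list[list[str]]:
    """All subsets of the covariate pool, including the intercept-only model."""
    sets: list[list[str]] = []
    for r in range(len(covariates) + 1):
        sets += [list(c) for c in itertools.combinations(covariates, r)]
    return sets


def fit_pike_glm(
    sites: pd.DataFrame,
    candidate_sets: list[list[str]] | None = None,
    covariates: list[str] | None = None,
) -> PikeGlm:
    """Fit candidate quasi-binomial GLMs to site PIKE and average them.

    `sites` needs illegal_carcasses, total_carcasses and the covariate columns.
    Fits use a logit link with var_weights = total carcasses and a Pearson
    dispersion estimate. Candidates are weighted by QAICc computed with the
    global (largest) model's dispersion; the averaged model is the
    weight-weighted coefficient vector with zeros substituted where a term is
    absent (full-model averaging).
    """
    if covariates is None:
        pool = sorted({c for s in (candidate_sets or []) for c in s})
        covariates = pool or [c for c in sites.columns
                              if c not in ("site_id", "illegal_carcasses",
                                           "total_carcasses")]
    if candidate_sets is None:
        candidate_sets = default_candidate_sets(covariates)
    if sites.empty:
        raise ValueError("no retained sites to fit the PIKE GLM")

    y = (sites["illegal_carcasses"] / sites["total_carcasses"]).to_numpy()
    totals = sites["total_carcasses"].to_numpy(dtype=float)
    n = len(sites)

    def design(terms):
        X = pd.DataFrame({"const": np.ones(n)})
        for t in terms:
            X[t] = sites[t].to_numpy(dtype=float)
        return X

    # global model supplies the dispersion for QAICc
    global_terms = tuple(max(candidate_sets, key=len))
    fits = []
    for terms in candidate_sets:
        key = tuple(terms)
        X = design(terms)
        try:
            # t-based inference, as is conventional when the dispersion is
            # estimated (quasi families)
            res = sm.GLM(y, X, family=sm.families.Binomial(),
                         var_weights=totals).fit(scale="X2", use_t=True)
            if not np.all(np.isfinite(res.params)):
                raise ValueError("non-finite coefficients")
        except Exception as exc:  # separation / singular design
            logger.warning("dropping PIKE candidate %s: %s", key, exc)
            continue
        fits.append((key, res))
    if not fits:
        raise RuntimeError("every PIKE GLM candidate failed to fit")

    global_fits = [r for k, r in fits if k == global_terms]
    c_hat = (float(global_fits[0].scale) if global_fits
             else float(max(r.scale for _, r in fits)))
    c_hat = max(c_hat, 1.0)  # QAIC convention: do not inflate fit for underdispersion

    cands = []
    for key, res in fits:
        k = len(res.params) + 1  # + dispersion
        quasi_ll = res.llf / c_hat
        qaicc = -2.0 * quasi_ll + 2 * k
        if n - k - 1 > 0:
            qaicc += 2 * k * (k + 1) / (n - k - 1)
        else:
            qaicc = np.inf
        cands.append({"terms": key, "params": res.params,
                      "cov": res.cov_params(), "qaicc": qaicc, "fit": res})
    finite = [c for c in cands if np.isfinite(c["qaicc"])]
    if not finite:
        raise RuntimeError("no admissible PIKE GLM candidate (n too small)")
    qmin = min(c["qaicc"] for c in finite)
    wsum = 0.0
    for c in cands:
        c["weight"] = (np.exp(-0.5 * (c["qaicc"] - qmin))
                       if np.isfinite(c["qaicc"]) else 0.0)
        wsum += c["weight"]
    for c in cands:
        c["weight"] /= wsum

    cols = ["const"] + list(covariates)
    avg = pd.Series(0.0, index=cols)
    for c in cands:
        for name, val in c["params"].items():
            avg[name] += c["weight"] * val
    return PikeGlm(covariates=list(covariates), candidates=cands,
                   dispersion=c_hat, avg_params=avg)


def predict_pike(model: PikeGlm, covariates: pd.Series | dict,
                 site_id: str = "") -> PikeEstimate:
    """Model-averaged PIKE prediction with an unconditional logit-scale SE.

    eta is the weight-averaged linear predictor over candidates; its SE is the
    model-averaging unconditional standard error
    sqrt( sum_m w_m * (var_m(eta) + (eta_m - eta_bar)^2) ), which folds
    between-model spread into the within-model variance.
    """
    x_full = model.design_row(covariates)
    names = ["const"] + model.covariates
    etas, variances, weights = [], [], []
    for c in model.candidates:
        idx = [names.index(nm) for nm in c["params"].index]
        x = x_full[idx]
        etas.append(float(x @ c["params"].to_numpy()))
        V = np.asarray(c["cov"])
        variances.append(float(x @ V @ x))
        weights.append(c["weight"])
    etas, variances, weights = map(np.asarray, (etas, variances, weights))
    eta_bar = float(np.sum(weights * etas))
    se = float(np.sqrt(np.sum(weights * (variances + (etas - eta_bar) ** 2))))
    return PikeEstimate(site_id=site_id, pike=float(expit(eta_bar)),
                        eta=eta_bar, eta_se=se, source="modeled")


def estimate_all_pike(
    areas: pd.DataFrame,
    carcasses: pd.DataFrame,
    covariates: list[str] | None = None,
    candidate_sets: list[list[str]] | None = None,
    years=(2002, 2014),
    min_total: int = 20,
) -> tuple[pd.DataFrame, PikeGlm]:
    """Empirical PIKE where monitored, modeled PIKE elsewhere.

    Areas whose area_id appears as a retained carcass site get empirical PIKE;
    the rest get averaged-GLM predictions from their covariates. Returns the
    per-area PIKE table (site_id, pike, eta, eta_se, source, carcasses_total)
    and the fitted averaged GLM.
    """
    if covariates is None:
        covariates = ["evi", "prop_12_water"]
    amalg = amalgamate_carcasses(carcasses, years=years)
    kept = filter_low_carcass_sites(amalg, min_total=min_total)
    train = kept.merge(areas, left_on="site_id", right_on="area_id", how="inner")
    glm = fit_pike_glm(train, candidate_sets=candidate_sets, covariates=covariates)

    kept_idx = kept.set_index("site_id")
    rows = []
    for _, a in areas.iterrows():
        aid = a["area_id"]
        if aid in kept_idx.index:
            rec = kept_idx.loc[aid]
            est = empirical_pike(int(rec["illegal_carcasses"]),
                                 int(rec["total_carcasses"]), site_id=aid)
        else:
            est = predict_pike(glm, a, site_id=aid)
        rows.append(est.__dict__)
    return pd.DataFrame(rows), glm
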