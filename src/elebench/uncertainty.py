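"""Nested Monte Carlo propagation of pipeline uncertainty.

Three uncertainty sources feed every benchmark prediction: the standard
errors of the stable densities extracted from time series, the
linear-predictor SEs of modeled PIKE values, and the coefficient
uncertainty of the stable-density GAM itself. They are combined in a
nested scheme: each outer draw perturbs the training densities (normal,
truncated at zero) and the modeled PIKE values (normal on the logit scale),
and refits the GAM; each inner draw simulates coefficients from the
refit's approximate multivariate-normal posterior and predicts stable
sizes for every area under current poaching and under the zero-poaching
benchmark, together with per-draw deficits and network totals. Medians,
SDs and asymmetric 95% prediction intervals (2.5th-97.5th percentiles)
are then read off the pooled n_outer x n_inner draws.

Empirical PIKE values are held fixed: only modeled PIKE is simulated.
Totals are computed within each draw, never from per-area summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .gam import GamFit, fit_gam

logger = logging.getLogger(__name__)


@dataclass
class McSummary:
    target_id: str
    median: float
    se: float
    lo_2_5: float
    hi_97_5: float
    n_draws: int


def summarize_mc(draws: np.ndarray, target_id: str,
                 min_draws: int = 100) -> McSummary:
    """Empirical median, SD and 2.5/97.5 percentiles of a draw vector."""
    draws = np.asarray(draws, dtype=float)
    if draws.size < min_draws:
        raise ValueError(f"need >= {min_draws} draws, got {draws.size}")
    lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
    se = float(np.std(draws, ddof=1)) if draws.size > 1 else 0.0
    return McSummary(target_id=target_id, median=float(med), se=se,
                     lo_2_5=float(lo), hi_97_5=float(hi),
                     n_draws=int(draws.size))


def _truncnorm_draw(rng, mean, sd):
    """Normal draws truncated at zero (elementwise; sd = 0 passes through)."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    out = mean.copy()
    pos = sd > 0
    if pos.any():
        a = (0.0 - mean[pos]) / sd[pos]
        out[pos] = stats.truncnorm.rvs(a, np.inf, loc=mean[pos], scale=sd[pos],
                                       random_state=rng)
    return out


def simulate_training_datasets(
    training: pd.DataFrame,
    pike_table: pd.DataFrame,
    n_outer: int,
    seed,
):
    """Yield n_outer perturbed (training, pike) dataset pairs.

    Training stable densities are redrawn from Normal(density, SE) truncated
    at zero; modeled PIKE values are redrawn as inv-logit(Normal(eta,
    eta_se)); empirical PIKE stays fixed. Each yielded training frame has
    stable_size updated to density x area and its pike column refreshed from
    the perturbed PIKE table.
    """
    rng = np.random.default_rng(seed)
    modeled = pike_table["source"].to_numpy() == "modeled"
    eta = pike_table["eta"].to_numpy(dtype=float)
    eta_se = pike_table["eta_se"].to_numpy(dtype=float)
    for _ in range(n_outer):
        dens = _truncnorm_draw(rng, training["stable_density"],
                               training["stable_density_se"])
        pike = pike_table["pike"].to_numpy(dtype=float).copy()
        if modeled.any():
            draw = rng.normal(eta[modeled], eta_se[modeled])
            pike[modeled] = expit(draw)
        pike_i = pike_table.copy()
        pike_i["pike"] = pike
        tr = training.copy()
        tr["stable_density"] = dens
        tr["stable_size"] = dens * tr["area_km2"].to_numpy(dtype=float)
        tr["pike"] = tr["area_id"].map(pike_i.set_index("site_id")["pike"]).to_numpy()
        yield tr, pike_i


@dataclass
class McResults:
    """Pooled draws and their summaries."""

    area_ids: np.ndarray
    sizes_current: np.ndarray   # (n_draws, n_areas) float32
    sizes_zero: np.ndarray
    deficits: np.ndarray
    totals_current: np.ndarray  # (n_draws,)
    totals_zero: np.ndarray
    net_deficits: np.ndarray
    n_outer: int
    n_inner: int
    n_failed_refits: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for j, aid in enumerate(self.area_ids):
            for name, mat in (("current_pike", self.sizes_current),
                              ("zero_pike", self.sizes_zero),
                              ("deficit", self.deficits)):
                s = summarize_mc(mat[:, j], f"{aid}:{name}", min_draws=1)
                rows.append(s.__dict__)
        for name, vec in (("total:current_pike", self.totals_current),
                          ("total:zero_pike", self.totals_zero),
                          ("total:net_deficit", self.net_deficits)):
            rows.append(summarize_mc(vec, name, min_draws=1).__dict__)
        return pd.DataFrame(rows)


def propagate(
    point_fit: GamFit,
    training: pd.DataFrame,
    pike_table: pd.DataFrame,
    areas: pd.DataFrame,
    n_outer: int = 1000,
    n_inner: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    max_failure_frac: float = 0.10,
    gcv_maxiter: int = 40,
) -> McResults:
    """Run the nested Monte Carlo around the fitted point GAM.

    Each outer refit keeps the point fit's candidate formula, warm-starts the
    GCV search at the point fit's smoothing parameters and re-estimates the
    NB dispersion; inner draws simulate coefficients from each refit's
    posterior. With n_inner = 1 the posterior mean is used instead of a
    random coefficient draw, so a run with all SEs zero and n_outer =
    n_inner = 1 reproduces the deterministic pipeline exactly.

    `areas` must carry a pike column giving each area's current (empirical or
    modeled point) PIKE; the per-draw PIKE dataset overrides it for modeled
    areas. Aborts if more than `max_failure_frac` of outer refits fail.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seed_outer, seed_inner = ss.spawn(2)
    rng_inner = np.random.default_rng(seed_inner)

    n_areas = len(areas)
    area_ids = areas["area_id"].to_numpy()
    recent = areas["recent_estimate"].to_numpy(dtype=float)
    log_area = np.log(areas["area_km2"].to_numpy(dtype=float))
    modeled_mask = (areas["area_id"].map(
        pike_table.set_index("site_id")["source"]).to_numpy() == "modeled")

    # with no input uncertainty every outer dataset equals the original and
    # the refit is identical to the point fit: reuse it (exact collapse)
    degenerate = (
        (training["stable_density_se"].to_numpy(dtype=float) == 0).all()
        and ((pike_table["eta_se"].to_numpy(dtype=float) == 0)
             | (pike_table["source"].to_numpy() == "empirical")).all())

    blocks_cur, blocks_zero = [], []
    n_failed = 0
    datasets = simulate_training_datasets(training, pike_table, n_outer, seed_outer)
    for i, (tr, pike_i) in enumerate(datasets):
        try:
            refit = point_fit if degenerate else fit_gam(
                tr, formula_id=point_fit.formula_id,
                lambda0=point_fit.lambdas,
                gcv_maxiter=gcv_maxiter, theta_iter=2)
        except Exception as exc:
            n_failed += 1
            logger.warning("outer refit %d failed: %s", i, exc)
            if n_failed > max_failure_frac * n_outer:
                raise RuntimeError(
                    f"{n_failed} of {i + 1} outer GAM refits failed") from exc
            continue

        if n_inner == 1:
            betas = refit.beta[None, :]
        else:
            try:
                betas = rng_inner.multivariate_normal(refit.beta, refit.Vp,
                                                      size=n_inner,
                                                      method="cholesky")
            except np.linalg.LinAlgError:
                betas = rng_inner.multivariate_normal(refit.beta, refit.Vp,
                                                      size=n_inner, method="svd")
        data_cur = areas.copy()
        pike_cur = data_cur["pike"].to_numpy(dtype=float).copy()
        pike_map = pike_i.set_index("site_id")["pike"]
        pike_cur[modeled_mask] = data_cur["area_id"].map(pike_map).to_numpy()[modeled_mask]
        data_cur["pike"] = pike_cur
        cur = refit.predict_size(data_cur, log_area, beta=betas)
        data_zero = data_cur.copy()
        data_zero["pike"] = 0.0
        zero = refit.predict_size(data_zero, log_area, beta=betas)
        blocks_cur.append(cur.astype(np.float32))
        blocks_zero.append(zero.astype(np.float32))

    if not blocks_cur:
        raise RuntimeError("all outer refits failed")
    sizes_current = np.vstack(blocks_cur)
    sizes_zero = np.vstack(blocks_zero)
    deficits = recent[None, :].astype(np.float32) - sizes_zero
    return McResults(
        area_ids=area_ids,
        sizes_current=sizes_current,
        sizes_zero=sizes_zero,
        deficits=deficits,
        totals_current=sizes_current.sum(axis=1),
        totals_zero=sizes_zero.sum(axis=1),
        net_deficits=deficits.sum(axis=1),
        n_outer=n_outer,
        n_inner=n_inner,
        n_failed_refits=n_failed,
    )
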