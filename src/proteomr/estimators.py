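"""Summary-data Mendelian randomization estimators.

All estimators consume per-variant harmonized association pairs: exposure
effects ``bx`` with standard errors ``bx_se`` and outcome effects ``by``
with ``by_se``, one entry per (approximately) independent instrument.

* :func:`wald_ratio` — single-instrument ratio estimate, delta-method SE.
* :func:`ivw_fixed` — fixed-effects inverse-variance weighted estimate;
  algebraically the weighted least-squares fit of ``by`` on ``bx`` through
  the origin with weights ``by_se**-2``. The primary estimator.
* :func:`weighted_median` — consistent when >50% of instrument weight is
  valid; SE by parametric bootstrap.
* :func:`weighted_mode` — consistent when the largest cluster of
  instruments is valid (plurality); kernel-density mode of the ratio
  estimates.
* :func:`mr_presso` — residual-sum-of-squares global test for horizontal
  pleiotropy, per-variant outlier detection, and outlier-corrected IVW.

The fixed-effects IVW assumes every instrument is valid (no horizontal
pleiotropy); the remaining estimators progressively relax that assumption
and serve as sensitivity analyses.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .exceptions import InsufficientInstrumentsError, UndefinedRatioError
from .types import MREstimate


def _as_arrays(*xs):
    arrs = [np.atleast_1d(np.asarray(x, dtype=float)) for x in xs]
    n = {a.shape[0] for a in arrs}
    if len(n) != 1:
        raise ValueError("estimator inputs must have equal length")
    return arrs


def _wald_p(beta: float, se: float) -> float:
    return float(2.0 * norm.sf(abs(beta / se))) if se > 0 else float("nan")


def pairs_arrays(pairs) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Extract (bx, bx_se, by, by_se) from a harmonized pairs DataFrame."""
    return (pairs["beta_exp"].to_numpy(float), pairs["se_exp"].to_numpy(float),
            pairs["beta_out"].to_numpy(float), pairs["se_out"].to_numpy(float))


def wald_ratio(bx: float, by: float, by_se: float, bx_se: float | None = None,
               second_order: bool = False) -> MREstimate:
    """Single-instrument causal estimate by/bx.

    The default SE is the first-order delta method, by_se/|bx|, which
    ignores exposure-side sampling error and matches the weighting used by
    the fixed-effects IVW. ``second_order=True`` adds the exposure-error
    term sqrt(by_se^2/bx^2 + by^2*bx_se^2/bx^4).
    """
    if bx == 0:
        raise UndefinedRatioError("Wald ratio undefined for zero exposure effect")
    beta = by / bx
    if second_order:
        if bx_se is None:
            raise ValueError("second_order SE requires bx_se")
        se = float(np.sqrt(by_se**2 / bx**2 + by**2 * bx_se**2 / bx**4))
    else:
        se = by_se / abs(bx)
    return MREstimate(beta=float(beta), se=float(se), pvalue=_wald_p(beta, se),
                      method="wald", n_instruments=1)


def ivw_fixed(bx, by, by_se) -> MREstimate:
    """Fixed-effects inverse-variance weighted estimate.

    beta = sum(bx*by/by_se^2) / sum(bx^2/by_se^2),
    se   = sum(bx^2/by_se^2)^(-1/2).

    Reduces exactly to the Wald ratio for a single instrument. Cochran's
    heterogeneity Q (and its chi-square p on n-1 df) is reported in
    ``diagnostics``.
    """
    bx, by, by_se = _as_arrays(bx, by, by_se)
    if bx.size == 0:
        raise InsufficientInstrumentsError("ivw_fixed requires at least one instrument")
    w = by_se**-2.0
    denom = float(np.sum(bx**2 * w))
    if denom == 0:
        raise UndefinedRatioError("all exposure effects are zero")
    if bx.size == 1:
        # same algebra as the Wald ratio; use its form so the reduction is exact
        beta = float(by[0] / bx[0])
        se = float(by_se[0] / abs(bx[0]))
    else:
        beta = float(np.sum(bx * by * w) / denom)
        se = denom**-0.5
    q = float(np.sum(w * (by - beta * bx) ** 2))
    diag = {"cochran_q": q, "q_df": int(bx.size - 1)}
    if bx.size > 1:
        from scipy.stats import chi2

        diag["q_pvalue"] = float(chi2.sf(q, bx.size - 1))
    return MREstimate(beta=beta, se=se, pvalue=_wald_p(beta, se),
                      method="ivw_fixed", n_instruments=int(bx.size), diagnostics=diag)


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: where cumulative standardized weight crosses 0.5."""
    order = np.argsort(ratios, kind="mergesort")
    r, w = ratios[order], weights[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w  # midpoint convention
    return float(np.interp(0.5, cum, r))


def weighted_median(bx, bx_se, by, by_se, bootstrap_reps: int = 1000,
                    seed: int | None = None) -> MREstimate:
    """Weighted median of the per-variant Wald ratios.

    Weights are the first-order inverse ratio variances bx^2/by_se^2,
    normalized to sum one. Consistent as long as valid instruments carry
    more than half the total weight. SE from a parametric bootstrap:
    bx and by are resampled from N(bx, bx_se) and N(by, by_se) per variant
    and the median recomputed; with ``bootstrap_reps=0`` the SE (and p)
    are NaN and only the point estimate is returned.
    """
    bx, bx_se, by, by_se = _as_arrays(bx, bx_se, by, by_se)
    if bx.size < 3:
        raise InsufficientInstrumentsError("weighted_median requires >= 3 instruments")
    ratios = by / bx
    weights = bx**2 / by_se**2
    beta = _weighted_median_point(ratios, weights)
    se = p = float("nan")
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        bx_s = rng.normal(bx, bx_se, size=(bootstrap_reps, bx.size))
        by_s = rng.normal(by, by_se, size=(bootstrap_reps, bx.size))
        boots = np.empty(bootstrap_reps)
        for i in range(bootstrap_reps):
            boots[i] = _weighted_median_point(by_s[i] / bx_s[i], bx_s[i] ** 2 / by_se**2)
        se = float(np.std(boots, ddof=1))
        p = _wald_p(beta, se)
    return MREstimate(beta=beta, se=se, pvalue=p, method="weighted_median",
                      n_instruments=int(bx.size), diagnostics={"bootstrap_reps": bootstrap_reps})


def _mode_bandwidth(ratios: np.ndarray, factor: float) -> float:
    """Modified Silverman rule on the ratio estimates: 0.9*min(sd, MADn)*n^(-1/5)."""
    s = np.std(ratios, ddof=1) if ratios.size > 1 else 0.0
    madn = 1.4826 * np.median(np.abs(ratios - np.median(ratios)))
    scale = min(x for x in (s, madn) if x > 0) if max(s, madn) > 0 else 0.0
    return factor * 0.9 * scale * ratios.size ** (-1 / 5)


def _weighted_mode_point(ratios: np.ndarray, weights: np.ndarray, factor: float,
                         grid_size: int = 512) -> float:
    h = _mode_bandwidth(ratios, factor)
    if h == 0.0 or np.ptp(ratios) == 0.0:
        # degenerate cluster: every ratio identical (or no spread to estimate)
        return float(np.median(ratios))
    w = weights / weights.sum()
    grid = np.linspace(ratios.min() - 2 * h, ratios.max() + 2 * h, grid_size)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def weighted_mode(bx, bx_se, by, by_se, bandwidth_factor: float = 1.0,
                  bootstrap_reps: int = 1000, seed: int | None = None) -> MREstimate:
    """Mode of the weighted kernel density over the per-variant Wald ratios.

    Weights as in :func:`weighted_median`; the normal-kernel bandwidth is
    ``bandwidth_factor`` times a modified Silverman rule based on the
    median absolute deviation of the ratios. Consistent when the largest
    group of instruments sharing a causal estimate is valid. SE by the
    same parametric bootstrap as the weighted median.
    """
    bx, bx_se, by, by_se = _as_arrays(bx, bx_se, by, by_se)
    if bx.size < 3:
        raise InsufficientInstrumentsError("weighted_mode requires >= 3 instruments")
    ratios = by / bx
    weights = bx**2 / by_se**2
    beta = _weighted_mode_point(ratios, weights, bandwidth_factor)
    se = p = float("nan")
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        bx_s = rng.normal(bx, bx_se, size=(bootstrap_reps, bx.size))
        by_s = rng.normal(by, by_se, size=(bootstrap_reps, bx.size))
        boots = np.empty(bootstrap_reps)
        for i in range(bootstrap_reps):
            boots[i] = _weighted_mode_point(by_s[i] / bx_s[i], bx_s[i] ** 2 / by_se**2,
                                            bandwidth_factor, grid_size=256)
        se = float(np.std(boots, ddof=1))
        p = _wald_p(beta, se)
    return MREstimate(beta=beta, se=se, pvalue=p, method="weighted_mode",
                      n_instruments=int(bx.size),
                      diagnostics={"bandwidth_factor": bandwidth_factor,
                                   "bootstrap_reps": bootstrap_reps})


def _loo_ivw(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slope for each index, vectorized."""
    s_xy = np.sum(bx * by * w)
    s_xx = np.sum(bx**2 * w)
    return (s_xy - bx * by * w) / (s_xx - bx**2 * w)


def _loo_ivw_matrix(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise leave-one-out IVW slopes for (nsim, n) matrices."""
    s_xy = np.sum(bx * by * w, axis=1, keepdims=True)
    s_xx = np.sum(bx**2 * w, axis=1, keepdims=True)
    return (s_xy - bx * by * w) / (s_xx - bx**2 * w)


def mr_presso(bx, bx_se, by, by_se, n_simulations: int = 1000,
              outlier_p: float = 0.05, seed: int | None = None) -> MREstimate:
    """Pleiotropy residual-sum-of-squares test with outlier correction.

    Three components:

    1. *Global test.* Observed RSS = sum_j w_j (by_j - b_(-j) bx_j)^2 with
       w_j = by_se_j^-2 and b_(-j) the leave-one-out IVW slope, compared
       against its null distribution from ``n_simulations`` parametric
       draws: by* ~ N(b_(-j) bx, by_se) with leave-one-out slopes
       recomputed per draw, conditioning on the observed exposure effects
       (the same convention as the fixed-effects weighting, and what keeps
       the test's type-I error at its nominal level). Empirical p with the
       +1 correction.
    2. *Outlier test.* Per-variant weighted squared residuals against
       their simulated null, Bonferroni-adjusted by n; variants below
       ``outlier_p`` are flagged.
    3. *Corrected estimate.* Fixed-effects IVW on the unflagged variants;
       identical to the full-set IVW when nothing is flagged. A distortion
       test (raw minus corrected estimate against random same-size
       removals) is reported when outliers were found.

    Diagnostics: ``global_rss``, ``global_pvalue``, ``outlier_indices``,
    ``outlier_pvalues``, ``raw_beta``, ``distortion``, ``distortion_pvalue``.
    """
    bx, bx_se, by, by_se = _as_arrays(bx, bx_se, by, by_se)
    n = bx.size
    if n < 4:
        raise InsufficientInstrumentsError("mr_presso requires >= 4 instruments")
    rng = np.random.default_rng(seed)
    w = by_se**-2.0

    loo = _loo_ivw(bx, by, w)
    res_obs = w * (by - loo * bx) ** 2
    rss_obs = float(res_obs.sum())

    bx_s = np.broadcast_to(bx, (n_simulations, n))
    by_s = rng.normal(loo * bx, by_se, size=(n_simulations, n))
    loo_s = _loo_ivw_matrix(bx_s, by_s, w)
    res_s = w * (by_s - loo_s * bx_s) ** 2
    rss_s = res_s.sum(axis=1)
    global_p = float((1 + np.sum(rss_s >= rss_obs)) / (1 + n_simulations))

    p_var = (1 + np.sum(res_s >= res_obs[None, :], axis=0)) / (1 + n_simulations)
    p_adj = np.minimum(1.0, p_var * n)
    flagged = np.flatnonzero(p_adj < outlier_p)

    raw = ivw_fixed(bx, by, by_se)
    diag = {"global_rss": rss_obs, "global_pvalue": global_p,
            "outlier_indices": flagged.tolist(),
            "outlier_pvalues": p_adj.tolist(), "raw_beta": raw.beta,
            "n_simulations": n_simulations}
    if flagged.size == 0 or n - flagged.size == 0:
        corrected = raw
        diag["distortion"] = 0.0
    else:
        keep = np.setdiff1d(np.arange(n), flagged)
        corrected = ivw_fixed(bx[keep], by[keep], by_se[keep])
        d_obs = raw.beta - corrected.beta
        d_sim = np.empty(n_simulations)
        for i in range(n_simulations):
            drop = rng.choice(n, size=flagged.size, replace=False)
            k = np.setdiff1d(np.arange(n), drop)
            wk = w[k]
            d_sim[i] = raw.beta - np.sum(bx[k] * by[k] * wk) / np.sum(bx[k] ** 2 * wk)
        diag["distortion"] = float(d_obs)
        diag["distortion_pvalue"] = float(
            (1 + np.sum(np.abs(d_sim) >= abs(d_obs))) / (1 + n_simulations))
    return MREstimate(beta=corrected.beta, se=corrected.se, pvalue=corrected.pvalue,
                      method="mr_presso", n_instruments=corrected.n_instruments,
                      diagnostics=diag)


def estimate_pairs(pairs, method: str = "ivw_fixed", **kwargs) -> MREstimate:
    """Dispatch an estimator over a harmonized pairs DataFrame.

    Uses the Wald ratio automatically for a single instrument when the
    IVW is requested (they coincide anyway).
    """
    bx, bx_se, by, by_se = pairs_arrays(pairs)
    if method == "ivw_fixed":
        if bx.size == 1:
            return wald_ratio(bx[0], by[0], by_se[0], bx_se[0])
        return ivw_fixed(bx, by, by_se)
    if method == "wald":
        return wald_ratio(bx[0], by[0], by_se[0], bx_se[0], **kwargs)
    if method == "weighted_median":
        return weighted_median(bx, bx_se, by, by_se, **kwargs)
    if method == "weighted_mode":
        return weighted_mode(bx, bx_se, by, by_se, **kwargs)
    if method == "mr_presso":
        return mr_presso(bx, bx_se, by, by_se, **kwargs)
    raise ValueError(f"unknown method {method!r}")
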