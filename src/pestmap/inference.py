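"""Spatial inference of application rates from state statistics.

State-level median application rates are regressed, one covariate at a
time, against state-mean environmental covariates (soil, climate,
agronomic and socio-economic fields). The five covariates with the
strongest correlation |R| are combined into a weighted average of linear
predictions, with the 95% mean-response confidence band providing the
high/low envelope:

    H = sum_k W_k * [alpha_k X_k + beta_k + CI_k(X_k)]
    L = sum_k W_k * [alpha_k X_k + beta_k - CI_k(X_k)]

with W_k proportional to |n_k R_k| and summing to 1. A bin-averaged
cross-validation harness scores the method with
rank = (1 - |R|) * 100 + NRMSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grids import GridSpec, RegionMask

DEFAULT_TOP_K = 5
DEFAULT_TOTAL_STATES = 48


@dataclass
class CovariateStack:
    """Named covariate grids, all aligned on one GridSpec; NaN = missing."""

    spec: GridSpec
    grids: dict[str, np.ndarray]

    def names(self) -> list[str]:
        return list(self.grids)


# ---------------------------------------------------------------------------
# harmonization


def _overlap_matrix(src_edges: np.ndarray, dst_edges: np.ndarray) -> np.ndarray:
    """(n_dst, n_src) matrix of interval-overlap lengths between two edge sets."""
    s0, s1 = src_edges[:-1], src_edges[1:]
    d0, d1 = dst_edges[:-1], dst_edges[1:]
    lo = np.maximum(np.minimum(s0, s1)[None, :], np.minimum(d0, d1)[:, None])
    hi = np.minimum(np.maximum(s0, s1)[None, :], np.maximum(d0, d1)[:, None])
    return np.clip(hi - lo, 0.0, None)


def harmonize(
    grid: np.ndarray, src: GridSpec, target: GridSpec, kind: str = "continuous"
) -> np.ndarray:
    """Regrid ``grid`` from ``src`` to ``target``.

    kind="continuous": overlap-area-weighted mean (conserves the mean,
    reproduces constants); kind="categorical": nearest cell centre;
    kind="extensive": overlap-area redistribution conserving the global sum
    (areas, masses). Latitude weighting uses sin(lat) so redistribution is
    exact on the sphere.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.shape != src.shape:
        raise ValueError("grid shape does not match source spec")
    if (
        src.lon_max <= target.lon_min
        or target.lon_max <= src.lon_min
        or src.lat_max <= target.lat_min
        or target.lat_max <= src.lat_min
    ):
        raise ValueError("source and target extents are disjoint")
    if (src.shape == target.shape) and kind != "extensive":
        return grid.copy()

    if kind == "categorical":
        lat_idx = np.clip(
            ((src.lat_max - target.lats()) / src.dlat - 0.5).round().astype(int),
            0,
            src.n_rows - 1,
        )
        lon_idx = np.clip(
            ((target.lons() - src.lon_min) / src.dlon - 0.5).round().astype(int),
            0,
            src.n_cols - 1,
        )
        return grid[np.ix_(lat_idx, lon_idx)]

    # overlap fractions in sin(lat) (true spherical band measure) and lon
    m_lat = _overlap_matrix(np.sin(np.deg2rad(src.lat_edges())), np.sin(np.deg2rad(target.lat_edges())))
    m_lon = _overlap_matrix(src.lon_edges(), target.lon_edges())
    if kind == "extensive":
        # fraction of each SOURCE cell falling in each target cell
        w_lat = m_lat / np.maximum(m_lat.sum(axis=0, keepdims=True), 1e-300)
        w_lon = m_lon / np.maximum(m_lon.sum(axis=0, keepdims=True), 1e-300)
        return w_lat @ np.nan_to_num(grid) @ w_lon.T
    if kind == "continuous":
        num = m_lat @ np.nan_to_num(grid) @ m_lon.T
        den = m_lat @ np.isfinite(grid).astype(float) @ m_lon.T
        with np.errstate(invalid="ignore"):
            out = num / den
        out[den <= 0] = np.nan
        return out
    raise ValueError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# state means and per-covariate fits


def state_covariate_means(stack: CovariateStack, mask: RegionMask) -> pd.DataFrame:
    """Unweighted mean of each covariate over each state's land cells.

    Missing (NaN) cells are excluded; a state with no finite cells for a
    covariate gets no row (it is dropped from that covariate's fit).
    Columns: covariate, state, mean.
    """
    land = mask.land()
    labels = mask.labels[land]
    ids = mask.region_ids()
    nbins = int(ids.max()) + 1 if ids.size else 0
    rows = []
    for name, grid in stack.grids.items():
        vals = np.asarray(grid, dtype=float)[land]
        ok = np.isfinite(vals)
        sums = np.bincount(labels[ok], weights=vals[ok], minlength=nbins)
        cnts = np.bincount(labels[ok], minlength=nbins)
        for rid in ids:
            if cnts[rid] > 0:
                rows.append({"covariate": name, "state": int(rid), "mean": sums[rid] / cnts[rid]})
    return pd.DataFrame(rows, columns=["covariate", "state", "mean"])


@dataclass
class CovariateFit:
    """Monovariate linear model APR = alpha*X + beta for one (ai, crop, X).

    Carries the sufficient statistics needed to evaluate the 95%
    mean-response confidence band at any X, the sample correlation R and
    the fraction of available states used (n_frac = n / total states).
    """

    ai: str
    crop: str
    covariate: str
    alpha: float  # kg/ha per covariate unit
    beta: float  # kg/ha
    r: float
    n: int
    n_frac: float
    x_bar: float
    sxx: float
    resid_var: float  # s^2 with n-2 dof
    slope_se: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.alpha * np.asarray(x, dtype=float) + self.beta


def fit_apr_covariate(
    apr: np.ndarray,
    x: np.ndarray,
    ai: str = "",
    crop: str = "",
    covariate: str = "",
    total_states: int = DEFAULT_TOTAL_STATES,
) -> CovariateFit | None:
    """OLS of state median APR on the state-mean covariate.

    Returns None with fewer than 3 complete states. R is defined as 0 when
    either variable has zero variance.
    """
    apr = np.asarray(apr, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(apr) & np.isfinite(x)
    y, xv = apr[ok], x[ok]
    n = int(ok.sum())
    if n < 3:
        return None
    x_bar = float(xv.mean())
    sxx = float(np.sum((xv - x_bar) ** 2))
    syy = float(np.sum((y - y.mean()) ** 2))
    if sxx == 0.0:
        alpha, beta, r = 0.0, float(y.mean()), 0.0
        resid = y - beta
    else:
        sxy = float(np.sum((xv - x_bar) * (y - y.mean())))
        alpha = sxy / sxx
        beta = float(y.mean() - alpha * x_bar)
        r = 0.0 if syy == 0.0 else sxy / np.sqrt(sxx * syy)
        resid = y - (alpha * xv + beta)
    resid_var = float(np.sum(resid**2) / (n - 2)) if n > 2 else 0.0
    slope_se = float(np.sqrt(resid_var / sxx)) if sxx > 0 else np.inf
    return CovariateFit(
        ai=ai,
        crop=crop,
        covariate=covariate,
        alpha=float(alpha),
        beta=beta,
        r=float(np.clip(r, -1.0, 1.0)),
        n=n,
        n_frac=n / total_states,
        x_bar=x_bar,
        sxx=sxx,
        resid_var=resid_var,
        slope_se=slope_se,
    )


def confidence_band(fit: CovariateFit, x: np.ndarray, level: float = 0.95) -> np.ndarray:
    """Half-width of the two-sided mean-response confidence band at x:
    t_{1-a/2, n-2} * s * sqrt(1/n + (x - x_bar)^2 / Sxx)."""
    if fit.n <= 2:
        raise ValueError("confidence band undefined for n <= 2")
    x = np.asarray(x, dtype=float)
    tcrit = stats.t.ppf(0.5 + level / 2.0, fit.n - 2)
    s = np.sqrt(fit.resid_var)
    if fit.sxx == 0.0:
        return np.full_like(x, tcrit * s * np.sqrt(1.0 / fit.n))
    return tcrit * s * np.sqrt(1.0 / fit.n + (x - fit.x_bar) ** 2 / fit.sxx)


@dataclass
class WeightSet:
    """Top-k covariates and their normalized weights for one (ai, crop)."""

    ai: str
    crop: str
    weights: dict[str, float]  # covariate -> W_k, sums to 1

    def names(self) -> list[str]:
        return list(self.weights)


def compute_weights(
    fits: list[CovariateFit], k: int = DEFAULT_TOP_K, log: list[str] | None = None
) -> WeightSet:
    """Select the top-k covariates by |R| and weight them by |n R|.

    Ties in |R| break lexicographically by covariate name. If every
    selected |R| is 0 the weights are equal (logged).
    """
    if not fits:
        raise ValueError("no fitted covariates")
    ranked = sorted(fits, key=lambda f: (-abs(f.r), f.covariate))[: min(k, len(fits))]
    raw = np.array([abs(f.n * f.r) for f in ranked])
    if raw.sum() == 0.0:
        if log is not None:
            log.append(
                f"compute_weights: all |R|=0 for ({ranked[0].ai},{ranked[0].crop}), equal weights"
            )
        w = np.full(len(ranked), 1.0 / len(ranked))
    else:
        w = raw / raw.sum()
    return WeightSet(
        ai=ranked[0].ai, crop=ranked[0].crop, weights={f.covariate: float(v) for f, v in zip(ranked, w)}
    )


@dataclass
class RawGlobalAPR:
    """Raw (pre-conditioning) high/low application-rate grids [kg/ha/yr]."""

    ai: str
    crop: str
    high: np.ndarray
    low: np.ndarray


def infer_raw_global(
    fits: dict[str, CovariateFit],
    weights: WeightSet,
    stack: CovariateStack,
    crop_present: np.ndarray,
    log: list[str] | None = None,
) -> RawGlobalAPR:
    """Weight-averaged high/low APR surfaces on cells where the crop exists.

    Each selected covariate contributes its linear prediction +/- its 95%
    confidence band evaluated at that cell's covariate value. Cells where a
    covariate is missing drop that term with cellwise weight
    renormalization (logged); cells without the crop are NaN. Both bounds
    are floored at 0.
    """
    shape = stack.spec.shape
    num_h = np.zeros(shape)
    num_l = np.zeros(shape)
    wsum = np.zeros(shape)
    any_missing = False
    for name, w in weights.weights.items():
        fit = fits[name]
        x = np.asarray(stack.grids[name], dtype=float)
        ok = np.isfinite(x)
        if not ok.all():
            any_missing = True
        pred = fit.predict(np.nan_to_num(x))
        ci = confidence_band(fit, np.nan_to_num(x))
        num_h += np.where(ok, w * (pred + ci), 0.0)
        num_l += np.where(ok, w * (pred - ci), 0.0)
        wsum += np.where(ok, w, 0.0)
    if any_missing and log is not None:
        log.append(
            f"infer_raw_global: missing covariate cells renormalized for ({weights.ai},{weights.crop})"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        high = np.clip(num_h / wsum, 0.0, None)
        low = np.clip(num_l / wsum, 0.0, None)
    off = ~np.asarray(crop_present, dtype=bool) | (wsum <= 0)
    high[off] = np.nan
    low[off] = np.nan
    return RawGlobalAPR(ai=weights.ai, crop=weights.crop, high=high, low=low)


# ---------------------------------------------------------------------------
# cross-validation harness


@dataclass
class CVReport:
    calib_frac: float
    n_cal: int
    n_val: int
    r: float
    nrmse: float  # percent of the validation-set value range
    order: int = 1

    @property
    def rank(self) -> float:
        return rank_statistic(self.r, self.nrmse)


def rank_statistic(r: float, nrmse: float) -> float:
    """Goodness-of-inference rank: (1 - |R|) * 100 + NRMSE. Lower is better."""
    return (1.0 - abs(r)) * 100.0 + nrmse


def bin_average_points(
    apr: np.ndarray, stack: CovariateStack, n_bins: int
) -> pd.DataFrame:
    """Reduce cell scatter to ``n_bins`` equal-count bin averages.

    Cells with a finite rate and all covariates finite are sorted along the
    rate axis and split into equal-count bins; each bin contributes one
    point carrying the mean rate and the mean of every covariate, so the
    points remain jointly usable by the multi-covariate combination.
    """
    apr = np.asarray(apr, dtype=float).ravel()
    cols = {name: np.asarray(g, dtype=float).ravel() for name, g in stack.grids.items()}
    ok = np.isfinite(apr)
    for v in cols.values():
        ok &= np.isfinite(v)
    apr = apr[ok]
    if apr.size < n_bins:
        raise ValueError("fewer valid cells than bins")
    order = np.argsort(apr, kind="stable")
    groups = np.array_split(order, n_bins)
    rows = []
    for g in groups:
        row = {"apr": apr[g].mean()}
        for name, v in cols.items():
            row[name] = v[ok][g].mean()
        rows.append(row)
    return pd.DataFrame(rows)


def crossvalidate(
    apr_truth: np.ndarray,
    stack: CovariateStack,
    calib_frac: float = 0.07,
    n_bins: int = 705,
    order: int = 1,
    seed: int = 0,
    top_k: int = DEFAULT_TOP_K,
) -> CVReport:
    """Bin-averaged calibration/validation test of the weighted monovariate
    combination.

    Points are bin averages of (rate, covariates); a seeded random split at
    ``calib_frac`` defines the calibration set. Per covariate a polynomial
    of the given order is fit on calibration points; weights come from
    calibration-sample |R| (all points share one n, which cancels). The
    combination predicts the validation points; R is the sample correlation
    between prediction and observation and NRMSE the RMSE as a percent of
    the validation-set value range.
    """
    pts = bin_average_points(apr_truth, stack, n_bins)
    rng = np.random.default_rng(seed)
    n = len(pts)
    n_cal = max(int(round(calib_frac * n)), order + 2)
    idx = rng.permutation(n)
    cal, val = idx[:n_cal], idx[n_cal:]
    if val.size == 0:
        raise ValueError("empty validation set")
    names = stack.names()
    coefs, rs = {}, {}
    y_cal = pts["apr"].to_numpy()[cal]
    for name in names:
        x_cal = pts[name].to_numpy()[cal]
        coefs[name] = np.polyfit(x_cal, y_cal, order)
        sx, sy = x_cal.std(), y_cal.std()
        rs[name] = 0.0 if sx == 0 or sy == 0 else float(np.corrcoef(x_cal, y_cal)[0, 1])
    chosen = sorted(names, key=lambda m: (-abs(rs[m]), m))[: min(top_k, len(names))]
    raw = np.array([abs(rs[m]) for m in chosen])
    w = np.full(len(chosen), 1.0 / len(chosen)) if raw.sum() == 0 else raw / raw.sum()

    y_val = pts["apr"].to_numpy()[val]
    pred = np.zeros(val.size)
    for wk, name in zip(w, chosen):
        pred += wk * np.polyval(coefs[name], pts[name].to_numpy()[val])
    resid = pred - y_val
    rng_y = float(y_val.max() - y_val.min())
    rmse = float(np.sqrt(np.mean(resid**2)))
    nrmse = 0.0 if rng_y == 0 else 100.0 * rmse / rng_y
    if np.std(pred) == 0 or np.std(y_val) == 0:
        r = 1.0 if rmse < 1e-12 else 0.0
    else:
        r = float(np.corrcoef(pred, y_val)[0, 1])
        if rmse < 1e-9 * max(1.0, abs(y_val).max()):
            r = 1.0
    return CVReport(
        calib_frac=calib_frac, n_cal=int(cal.size), n_val=int(val.size), r=r, nrmse=nrmse, order=order
    )
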