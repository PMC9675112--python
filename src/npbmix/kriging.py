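"""Exposure assessment: biweekly metrics, ordinary kriging, pregnancy averages.

Mirrors the usual air-pollution exposure-assignment chain: daily monitor
readings (24-h means for PM2.5 and temperature, daily 8-h maxima for ozone)
are averaged to biweekly values per monitor, interpolated to target points
(census-tract centroids) by ordinary kriging against a fitted semivariogram,
and finally averaged over each pregnancy with day-of-overlap weights.

Coordinates are projected planar km with Euclidean distances. The biweekly
calendar is a sequence of consecutive 14-day blocks anchored at 2009-01-01.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "VariogramModel",
    "daily_8h_max",
    "biweekly_aggregate",
    "biweekly_periods",
    "empirical_semivariogram",
    "fit_variogram",
    "krige_point",
    "pregnancy_average",
    "assign_pregnancy_exposure",
]

log = logging.getLogger(__name__)

BIWEEK_ANCHOR = date(2009, 1, 1)

# completeness rules (conventions; the data source is silent)
MIN_HOURS_PER_DAY = 18  # of 24, for a daily 8-h max to be valid
MIN_HOURS_PER_WINDOW = 6  # of 8, for one window mean to count
MIN_DAYS_PER_BIWEEK = 1


@dataclass(frozen=True)
class VariogramModel:
    """Isotropic semivariogram: gamma(h) = nugget + partial_sill * f(h/range).

    f is 1 - exp(-h/range) (exponential) or the spherical ramp; gamma(0) is
    the nugget, treated as measurement-error variance, so kriging is exact
    at data sites only when nugget = 0.
    """

    family: str  # "exponential" | "spherical"
    nugget: float
    partial_sill: float
    range_km: float

    def __post_init__(self) -> None:
        if self.family not in ("exponential", "spherical"):
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0 or self.range_km <= 0:
            raise ValueError("require nugget >= 0, partial_sill >= 0, range > 0")

    def semivariance(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        if self.family == "exponential":
            f = 1.0 - np.exp(-h / self.range_km)
        else:
            r = np.minimum(h / self.range_km, 1.0)
            f = 1.5 * r - 0.5 * r**3
        return self.nugget + self.partial_sill * f


def daily_8h_max(hourly_values) -> float:
    """Maximum over contiguous 8-hour window means of one day's 24 hours.

    Returns NaN (missing sentinel) when the day has fewer than 18 non-missing
    hours, or when no window reaches 6 non-missing hours.
    """
    v = np.asarray(hourly_values, dtype=float)
    if v.shape != (24,):
        raise ValueError("expected exactly 24 hourly values (use NaN for missing)")
    ok = np.isfinite(v)
    if ok.sum() < MIN_HOURS_PER_DAY:
        return float("nan")
    best = -math.inf
    for start in range(17):  # windows 0-7 .. 16-23
        w = v[start : start + 8]
        wok = ok[start : start + 8]
        if wok.sum() >= MIN_HOURS_PER_WINDOW:
            best = max(best, float(w[wok].mean()))
    return best if best > -math.inf else float("nan")


def biweekly_aggregate(daily_values, metric: str = "mean24h") -> float:
    """Mean of available daily metric values within one 14-day window.

    ``daily_values`` is the 14 ordered daily values (already the daily 8-h
    max series when metric = "mean_of_daily_8h_max"); NaN marks missing days.
    """
    if metric not in ("mean24h", "mean_of_daily_8h_max"):
        raise ValueError(f"unknown biweekly metric {metric!r}")
    v = np.asarray(daily_values, dtype=float)
    if v.size != 14:
        raise ValueError("a biweekly window holds exactly 14 daily values")
    ok = np.isfinite(v)
    if ok.sum() < MIN_DAYS_PER_BIWEEK:
        return float("nan")
    return float(v[ok].mean())


def biweekly_periods(first: date, last: date, anchor: date = BIWEEK_ANCHOR):
    """Consecutive 14-day [start, end] blocks covering [first, last]."""
    k0 = (first - anchor).days // 14
    k1 = (last - anchor).days // 14
    return [
        (anchor + timedelta(days=14 * k), anchor + timedelta(days=14 * k + 13))
        for k in range(k0, k1 + 1)
    ]


def empirical_semivariogram(
    coords: np.ndarray, values: np.ndarray, bin_edges
) -> pd.DataFrame:
    """Classical (Matheron) binned semivariogram of one spatial snapshot.

    Per bin: mean pair distance, semivariance (1/2N) * sum (v_i - v_j)^2 over
    pairs whose separation falls in the bin, and the pair count. Empty bins
    keep count 0 and NaN semivariance.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(coords) < 2:
        raise ValueError("need at least 2 monitors")
    d = pdist(coords)
    dv2 = pdist(values[:, None], metric="sqeuclidean")
    edges = np.asarray(bin_edges, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (d >= lo) & (d < hi)
        n = int(sel.sum())
        rows.append(
            {
                "lag": float(d[sel].mean()) if n else (lo + hi) / 2.0,
                "semivariance": float(dv2[sel].sum() / (2.0 * n)) if n else float("nan"),
                "n_pairs": n,
            }
        )
    return pd.DataFrame(rows)


def fit_variogram(empirical: pd.DataFrame, family: str = "exponential") -> VariogramModel:
    """Weighted least squares fit (weights = pair counts) of a semivariogram.

    Requires >= 3 non-empty bins. Parameters are bounded to nugget >= 0,
    partial sill >= 0, range > 0.
    """
    emp = empirical[(empirical["n_pairs"] > 0) & np.isfinite(empirical["semivariance"])]
    if len(emp) < 3:
        raise ValueError(
            f"need >= 3 non-empty semivariogram bins, got {len(emp)}:\n{empirical}"
        )
    h = emp["lag"].to_numpy()
    g = emp["semivariance"].to_numpy()
    w = np.sqrt(emp["n_pairs"].to_numpy().astype(float))

    def resid(theta):
        nug, psill, rng_ = theta
        m = VariogramModel(family, max(nug, 0.0), max(psill, 0.0), max(rng_, 1e-9))
        return w * (m.semivariance(h) - g)

    g_span = max(g.max() - g.min(), 1e-12)
    x0 = np.array([max(g.min(), 1e-6), g_span, max(h.max() / 3.0, 1e-3)])
    sol = least_squares(
        resid,
        x0,
        bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not sol.success:
        raise RuntimeError(f"variogram fit failed: {sol.message}\n{empirical}")
    nug, psill, rng_ = sol.x
    # flat variograms collapse to pure nugget; keep a tiny sill for validity
    return VariogramModel(family, float(nug), float(max(psill, 0.0)), float(rng_))


def _dedupe(coords: np.ndarray, values: np.ndarray, tol: float = 1e-9):
    """Average co-located monitors so the kriging matrix is nonsingular."""
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.lexsort(coords.T)
    keep_c, keep_v = [], []
    for i in order:
        if keep_c and np.hypot(*(coords[i] - keep_c[-1])) <= tol:
            group = keep_v[-1]
            group.append(values[i])
        else:
            keep_c.append(coords[i])
            keep_v.append([values[i]])
    return np.array(keep_c), np.array([np.mean(g) for g in keep_v])


def krige_point(
    model: VariogramModel,
    coords: np.ndarray,
    values: np.ndarray,
    target,
    return_weights: bool = False,
):
    """Ordinary kriging at one target point.

    Solves the standard system with a Lagrange multiplier enforcing that
    weights sum to 1; returns (prediction, kriging variance). The variance is
    clamped at 0 (with a logged warning) if round-off drives it negative.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    values = np.asarray(values, dtype=float)
    target = np.asarray(target, dtype=float)
    if len(coords) != len(values):
        raise ValueError("coords and values length mismatch")
    if len(coords) == 0:
        raise ValueError("need at least one monitor")
    if len(coords) == 1:
        out = (float(values[0]), float(model.nugget))
        return (*out, np.array([1.0])) if return_weights else out

    coords, values = _dedupe(coords, values)
    m = len(coords)
    if m == 1:
        out = (float(values[0]), float(model.nugget))
        return (*out, np.array([1.0])) if return_weights else out
    gamma = model.semivariance(squareform(pdist(coords)))
    np.fill_diagonal(gamma, model.semivariance(0.0))
    a = np.zeros((m + 1, m + 1))
    a[:m, :m] = gamma
    a[:m, m] = 1.0
    a[m, :m] = 1.0
    g0 = model.semivariance(cdist(coords, target[None, :]).ravel())
    b = np.append(g0, 1.0)
    try:
        sol = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular kriging system even after deduplication: {err}"
        ) from err
    wgt, mu = sol[:m], sol[m]
    pred = float(wgt @ values)
    var = float(wgt @ g0 + mu)
    if var < 0.0:
        if var < -1e-8:
            log.warning("kriging variance %.3e clamped to 0", var)
        var = 0.0
    if return_weights:
        return pred, var, wgt
    return pred, var


def pregnancy_average(
    periods: list[tuple[date, date]],
    values,
    conception: date,
    delivery: date,
) -> float:
    """Day-of-overlap weighted mean of biweekly predictions over a pregnancy.

    ``periods`` are inclusive [start, end] date pairs aligned with ``values``.
    NaN predictions are dropped; returns NaN if nothing overlaps.
    """
    if delivery <= conception:
        raise ValueError("delivery must be after conception")
    vals = np.asarray(values, dtype=float)
    if len(periods) != len(vals):
        raise ValueError("periods and values length mismatch")
    total_w = 0.0
    total = 0.0
    for (start, end), v in zip(periods, vals):
        overlap = (min(end, delivery) - max(start, conception)).days + 1
        if overlap > 0 and np.isfinite(v):
            total_w += overlap
            total += overlap * v
    return total / total_w if total_w > 0 else float("nan")


def assign_pregnancy_exposure(
    monitors: pd.DataFrame,
    targets: pd.DataFrame,
    metric: str = "mean24h",
    family: str = "exponential",
    bin_edges=None,
) -> pd.DataFrame:
    """Full chain: biweekly per-monitor metrics -> kriged biweekly surfaces at
    each target -> pregnancy averages.

    ``monitors``: long table (monitor_id, x_km, y_km, date, value) of daily
    values (pass the daily 8-h max series for ozone). ``targets``: one row
    per dyad with dyad_id, x_km, y_km, conception_date, delivery_date.
    A single variogram is fitted to the pooled standardized biweekly
    snapshots and reused across biweeks.
    """
    monitors = monitors.copy()
    monitors["date"] = pd.to_datetime(monitors["date"]).dt.date
    first, last = targets["conception_date"].min(), targets["delivery_date"].max()
    periods = biweekly_periods(first, last)
    sites = monitors.groupby("monitor_id")[["x_km", "y_km"]].first()
    coords = sites.to_numpy()

    # per-monitor biweekly metric values
    biweekly = np.full((len(periods), len(sites)), np.nan)
    by_monitor = {mid: grp.set_index("date")["value"] for mid, grp in monitors.groupby("monitor_id")}
    for pi, (start, end) in enumerate(periods):
        days = [start + timedelta(days=k) for k in range(14)]
        for si, mid in enumerate(sites.index):
            series = by_monitor[mid]
            daily = [series.get(d, float("nan")) for d in days]
            biweekly[pi, si] = biweekly_aggregate(daily, metric=metric)

    if bin_edges is None:
        span = pdist(coords).max()
        bin_edges = np.linspace(1e-6, span, 9)
    # pool snapshots (centered per biweek) for one variogram fit
    pooled = None
    for row in biweekly:
        ok = np.isfinite(row)
        if ok.sum() >= 2:
            emp = empirical_semivariogram(coords[ok], row[ok] - row[ok].mean(), bin_edges)
            emp = emp.assign(sv_w=emp["semivariance"] * emp["n_pairs"])
            pooled = emp if pooled is None else pd.concat([pooled, emp])
    agg = pooled.groupby(pooled.index).agg(
        lag=("lag", "mean"), sv_w=("sv_w", "sum"), n_pairs=("n_pairs", "sum")
    )
    agg["semivariance"] = agg["sv_w"] / agg["n_pairs"].where(agg["n_pairs"] > 0)
    model = fit_variogram(agg[["lag", "semivariance", "n_pairs"]], family=family)

    rows = []
    for _, t in targets.iterrows():
        preds = np.full(len(periods), np.nan)
        for pi in range(len(periods)):
            ok = np.isfinite(biweekly[pi])
            if ok.sum() >= 1:
                preds[pi], _ = krige_point(
                    model, coords[ok], biweekly[pi, ok], (t["x_km"], t["y_km"])
                )
        avg = pregnancy_average(periods, preds, t["conception_date"], t["delivery_date"])
        rows.append({"dyad_id": t["dyad_id"], "pregnancy_avg": avg})
    return pd.DataFrame(rows)
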