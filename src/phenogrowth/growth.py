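"""Growth-rate analysis of predicted fresh biomass (PFB) trajectories.

Each pot's daily PFB series is smoothed with a cubic smoothing spline; the
spline's analytic first derivative gives the pointwise absolute growth rate
AGR(t) = S'(t) (g d^-1) and relative growth rate RGR(t) = S'(t)/S(t)
(g g^-1 d^-1). Interval rates over a window (tj, tk) use the smoothed PFB at
the endpoints:

    AGR(tj, tk) = (PFB(tk) - PFB(tj)) / (tk - tj)
    RGR(tj, tk) = (ln PFB(tk) - ln PFB(tj)) / (tk - tj)

RGR is window-invariant (equal to the rate constant) for exponential growth.
Smoothing strength is expressed as equivalent degrees of freedom, default
min(5, distinct days - 1); the penalty is solved to match that df. Series
with fewer than four distinct days cannot be smoothed: all smoothed values
and derivatives are set to missing and a warning is recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import brentq

__all__ = [
    "GrowthSeries",
    "fit_growth_spline",
    "agr_interval",
    "rgr_interval",
    "windowed_rates",
    "compute_growth",
    "DEFAULT_WINDOWS",
    "PFB_FLOOR_G",
]

DEFAULT_WINDOWS = ((2, 6), (5, 12), (2, 12))
PFB_FLOOR_G = 0.01  # grams; guards the log in RGR against clipped predictions


# cache: (x tuple, target df) -> lambda, shared across plants imaged on the
# same days
_LAM_CACHE: dict = {}


def _effective_df(x: np.ndarray, lam: float) -> float:
    """Trace of the smoother matrix, by smoothing the unit vectors."""
    n = len(x)
    tr = 0.0
    eye = np.eye(n)
    for i in range(n):
        tr += float(make_smoothing_spline(x, eye[i], lam=lam)(x[i]))
    return tr


def _lambda_for_df(x: np.ndarray, df: float) -> float:
    key = (tuple(np.round(x, 9)), round(df, 6))
    if key in _LAM_CACHE:
        return _LAM_CACHE[key]
    lo, hi = 1e-10, 1e10
    # df is monotone decreasing in lambda: df(lo) ~ n, df(hi) ~ 2
    f = lambda loglam: _effective_df(x, 10.0**loglam) - df
    flo, fhi = f(np.log10(lo)), f(np.log10(hi))
    if flo <= 0:  # even interpolation has fewer df than requested
        lam = lo
    elif fhi >= 0:  # even a line has more df than requested
        lam = hi
    else:
        lam = 10.0 ** brentq(f, np.log10(lo), np.log10(hi), xtol=1e-3)
    _LAM_CACHE[key] = lam
    return lam


@dataclass
class SplineFit:
    ok: bool
    spline: object = None
    deriv: object = None
    t_min: float = np.nan
    t_max: float = np.nan
    lam: float = np.nan
    df: float = np.nan

    def pfb(self, t):
        self._check(t)
        return np.maximum(PFB_FLOOR_G, self.spline(t))

    def agr(self, t):
        self._check(t)
        return self.deriv(t)

    def rgr(self, t):
        return self.agr(t) / self.pfb(t)

    def _check(self, t):
        if not self.ok:
            raise ValueError("spline fit unavailable (< 4 distinct days)")
        t = np.asarray(t, dtype=float)
        if np.any(t < self.t_min - 1e-9) or np.any(t > self.t_max + 1e-9):
            raise ValueError(
                f"extrapolation refused: t outside [{self.t_min}, {self.t_max}]"
            )


def fit_growth_spline(days, pfb, df: float | None = None, lam: float | None = None) -> SplineFit:
    """Cubic smoothing spline of PFB against day.

    Missing PFB values are dropped before fitting. With fewer than four
    distinct day values the fit is refused: a warning is issued and an
    unusable fit (all values/derivatives missing) is returned.
    """
    days = np.asarray(days, dtype=float)
    pfb = np.asarray(pfb, dtype=float)
    keep = np.isfinite(days) & np.isfinite(pfb)
    days, pfb = days[keep], pfb[keep]
    order = np.argsort(days)
    days, pfb = days[order], pfb[order]
    ux, inv = np.unique(days, return_inverse=True)
    if len(ux) < 4:
        warnings.warn(
            f"only {len(ux)} distinct day values; smoothed values and "
            "derivatives set to missing",
            stacklevel=2,
        )
        return SplineFit(ok=False)
    # average replicate observations on the same day
    uy = np.bincount(inv, weights=pfb) / np.bincount(inv)
    target_df = df if df is not None else min(5.0, len(ux) - 1)
    if lam is None:
        lam = _lambda_for_df(ux, float(target_df))
    spline = make_smoothing_spline(ux, uy, lam=lam)
    return SplineFit(
        ok=True,
        spline=spline,
        deriv=spline.derivative(),
        t_min=float(ux[0]),
        t_max=float(ux[-1]),
        lam=float(lam),
        df=float(target_df),
    )


def agr_interval(pfb_tj: float, pfb_tk: float, tj: float, tk: float) -> float:
    if tk <= tj:
        raise ValueError(f"window requires tk > tj, got ({tj}, {tk})")
    return (pfb_tk - pfb_tj) / (tk - tj)


def rgr_interval(pfb_tj: float, pfb_tk: float, tj: float, tk: float) -> float:
    if tk <= tj:
        raise ValueError(f"window requires tk > tj, got ({tj}, {tk})")
    if pfb_tj <= 0 or pfb_tk <= 0:
        raise ValueError("RGR requires positive PFB at both endpoints")
    return (np.log(pfb_tk) - np.log(pfb_tj)) / (tk - tj)


@dataclass
class GrowthSeries:
    plant_id: str
    days: np.ndarray
    pfb: np.ndarray
    fit: SplineFit = field(default=None)

    @classmethod
    def from_observations(cls, plant_id, days, pfb, df=None):
        return cls(
            plant_id=str(plant_id),
            days=np.asarray(days, dtype=float),
            pfb=np.asarray(pfb, dtype=float),
            fit=fit_growth_spline(days, pfb, df=df),
        )

    def smoothed(self) -> pd.DataFrame:
        if not self.fit.ok:
            return pd.DataFrame(
                {
                    "plant_id": self.plant_id,
                    "day": self.days,
                    "pfb_smooth": np.nan,
                    "agr": np.nan,
                    "rgr": np.nan,
                }
            )
        s = self.fit.pfb(self.days)
        a = self.fit.agr(self.days)
        return pd.DataFrame(
            {
                "plant_id": self.plant_id,
                "day": self.days,
                "pfb_smooth": s,
                "agr": a,
                "rgr": a / s,
            }
        )


def windowed_rates(series: GrowthSeries, windows=DEFAULT_WINDOWS) -> pd.DataFrame:
    """Interval AGR/RGR from smoothed PFB evaluated at window endpoints."""
    rows = []
    for tj, tk in windows:
        if tk <= tj:
            raise ValueError(f"degenerate window ({tj}, {tk})")
        if series.fit.ok:
            pj = float(series.fit.pfb(tj))
            pk = float(series.fit.pfb(tk))
            agr = agr_interval(pj, pk, tj, tk)
            rgr = rgr_interval(max(pj, PFB_FLOOR_G), max(pk, PFB_FLOOR_G), tj, tk)
        else:
            agr = rgr = np.nan
        rows.append(
            {
                "plant_id": series.plant_id,
                "window": f"{tj}:{tk}",
                "t_start": tj,
                "t_end": tk,
                "AGR": agr,
                "RGR": rgr,
            }
        )
    return pd.DataFrame(rows)


def compute_growth(
    pfb_table: pd.DataFrame,
    windows=DEFAULT_WINDOWS,
    df: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Windowed AGR/RGR and smoothed daily series for every plant.

    ``pfb_table`` needs columns plant_id, day, pfb_g (the predict-biomass
    output). Returns (rates long table, smoothed series table).
    """
    rates, smooth = [], []
    for pid, grp in pfb_table.groupby("plant_id", sort=True):
        series = GrowthSeries.from_observations(
            pid, grp["day"].to_numpy(), grp["pfb_g"].to_numpy(), df=df
        )
        rates.append(windowed_rates(series, windows))
        smooth.append(series.smoothed())
    return (
        pd.concat(rates, ignore_index=True),
        pd.concat(smooth, ignore_index=True),
    )
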