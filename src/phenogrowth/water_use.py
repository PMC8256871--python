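"""Water bookkeeping: daily water use, % field capacity, water-use indices.

Daily water use of a pot is the weight lost between the previous day's
post-watering weight and today's pre-watering weight — the combined
transpiration and soil-surface evaporation, uncorrected. Cumulative water
use WUCum is its running sum from stress onset. The three water-use indices
relate biomass (or growth rate) to the water consumed:

    WUI_BM(t)       = 1000 * PFB(t) / WUCum(t)        [mg ml^-1]
    WUI_AGR(tj,tk)  = AGR(tj,tk) / WU(tj,tk)          [g d^-1 ml^-1]
    WUI_RGR(tj,tk)  = RGR(tj,tk) / WU(tj,tk)          [g g^-1 d^-1 ml^-1]

where WU(tj, tk) is the water used within the window. Field capacity is
assessed gravimetrically: FC = saturated-drained weight - dry weight, and the
watering target at fraction f is dry weight + f * FC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import RangeError, WateringLedger

__all__ = [
    "field_capacity",
    "daily_water_use",
    "percent_fc_series",
    "wui_bm",
    "wui_agr",
    "wui_rgr",
    "window_water_use",
    "compute_wui",
    "WaterSeries",
]


def field_capacity(
    dry_weight_g: float, saturated_drained_weight_g: float, fractions=(0.8, 0.5)
) -> dict:
    """Gravimetric FC and target pot weights per %FC fraction.

    Default fractions are the well-watered (80%) and stressed (50%) targets.
    """
    if saturated_drained_weight_g < dry_weight_g:
        raise RangeError("saturated-drained weight below dry weight")
    fc = saturated_drained_weight_g - dry_weight_g
    return {
        "fc_g": fc,
        "targets": {f: dry_weight_g + f * fc for f in fractions},
    }


@dataclass
class WaterSeries:
    """Per-pot daily water use (ml d^-1) and cumulative use (ml)."""

    data: pd.DataFrame  # pot_id, day, wu_ml, wucum_ml, gap_filled, floored

    def for_pot(self, pot_id: str) -> pd.DataFrame:
        return self.data[self.data["pot_id"] == str(pot_id)]


def daily_water_use(ledger: WateringLedger) -> WaterSeries:
    """WU on day d = weight_after(d-1) - weight_before(d).

    Gaps in the day sequence spread the observed loss uniformly over the
    missing days (flagged); negative computed losses are floored at 0 and
    flagged as data-quality issues.
    """
    rows = []
    for pot, grp in ledger.data.groupby("pot_id", sort=True):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy()
        before = grp["weight_before_g"].to_numpy(dtype=float)
        after = grp["weight_after_g"].to_numpy(dtype=float)
        for i in range(1, len(days)):
            span = int(days[i] - days[i - 1])
            loss = after[i - 1] - before[i]
            floored = loss < 0
            loss = max(0.0, loss)
            for j in range(span):  # uniform spreading over a gap
                rows.append(
                    {
                        "pot_id": pot,
                        "day": int(days[i - 1]) + j + 1,
                        "wu_ml": loss / span,
                        "gap_filled": span > 1,
                        "floored": floored,
                    }
                )
    df = pd.DataFrame(rows)
    df["wucum_ml"] = df.groupby("pot_id")["wu_ml"].cumsum()
    return WaterSeries(
        df[["pot_id", "day", "wu_ml", "wucum_ml", "gap_filled", "floored"]]
    )


def percent_fc_series(
    ledger: WateringLedger,
    fc_g: float,
    dry_soil_weight_g: float | None = None,
    tare_g: float | None = None,
) -> pd.DataFrame:
    """%FC(d) = 100 * (weight_before(d) - tare - dry soil) / FC per pot-day."""
    if fc_g <= 0:
        raise RangeError("field capacity must be positive")
    tare = ledger.tare_g if tare_g is None else tare_g
    dry = ledger.dry_soil_weight_g if dry_soil_weight_g is None else dry_soil_weight_g
    df = ledger.data[["pot_id", "day"]].copy()
    water = ledger.data["weight_before_g"] - tare - dry
    df["percent_fc"] = 100.0 * water / fc_g
    df["negative_flag"] = water < 0
    return df


def wui_bm(pfb_g: float, wucum_ml: float) -> float:
    """Biomass per unit cumulative water, mg ml^-1."""
    if wucum_ml <= 0:
        raise ZeroDivisionError("WUCum must be positive for WUI_BM")
    return 1000.0 * pfb_g / wucum_ml


def wui_agr(agr: float, wu_interval_ml: float) -> float:
    if wu_interval_ml <= 0:
        raise ZeroDivisionError("interval water use must be positive for WUI_AGR")
    return agr / wu_interval_ml


def wui_rgr(rgr: float, wu_interval_ml: float) -> float:
    if wu_interval_ml <= 0:
        raise ZeroDivisionError("interval water use must be positive for WUI_RGR")
    return rgr / wu_interval_ml


def window_water_use(series: WaterSeries, pot_id: str, tj: int, tk: int) -> float:
    """Water used within (tj, tk]: sum of daily WU for tj < day <= tk."""
    pot = series.for_pot(pot_id)
    sel = pot[(pot["day"] > tj) & (pot["day"] <= tk)]
    return float(sel["wu_ml"].sum())


def compute_wui(
    pfb_table: pd.DataFrame,
    rates_table: pd.DataFrame,
    water: WaterSeries,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily WUI_BM plus windowed WUI_AGR / WUI_RGR per pot.

    ``pfb_table``: plant_id, day, pfb_g. ``rates_table``: windowed_rates
    output (plant_id, window, t_start, t_end, AGR, RGR). Returns
    (daily table, windowed table); indices with zero water in the
    denominator are left missing.
    """
    daily = pfb_table.merge(
        water.data[["pot_id", "day", "wu_ml", "wucum_ml"]],
        left_on=["plant_id", "day"],
        right_on=["pot_id", "day"],
        how="inner",
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        daily["WUI_BM"] = np.where(
            daily["wucum_ml"] > 0,
            1000.0 * daily["pfb_g"] / daily["wucum_ml"],
            np.nan,
        )
    daily = daily[["plant_id", "day", "pfb_g", "wu_ml", "wucum_ml", "WUI_BM"]]

    rows = []
    for r in rates_table.itertuples():
        wu = window_water_use(water, r.plant_id, int(r.t_start), int(r.t_end))
        rows.append(
            {
                "plant_id": r.plant_id,
                "window": r.window,
                "t_start": r.t_start,
                "t_end": r.t_end,
                "AGR": r.AGR,
                "RGR": r.RGR,
                "wu_window_ml": wu,
                "WUI_AGR": r.AGR / wu if wu > 0 else np.nan,
                "WUI_RGR": r.RGR / wu if wu > 0 else np.nan,
            }
        )
    return daily, pd.DataFrame(rows)
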