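"""End-to-end pipeline: simulate/load -> models -> growth -> water -> genetics.

One config drives the whole protocol: evaluate the eight biomass-prediction
families on harvest-day features, select the final model, predict daily
fresh biomass, smooth and differentiate the trajectories, convert the
watering ledger into water-use series and indices, estimate broad-sense
heritability of a derived trait, and attach Duncan letters to genotype
means. All intermediates are written as CSV/JSON into the output directory;
results are deterministic under a fixed seed and the config hash is recorded
in the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_io
from .biomass_models import (
    ALL_FAMILIES,
    Family,
    ModelEvaluation,
    ResampleSpec,
    _harvest_design,
    crossvalidate_final,
    evaluate_models,
    fit_model,
    predict_biomass,
    select_model,
)
from .growth import DEFAULT_WINDOWS, compute_growth
from .quant_genetics import duncan_mrt, heritability_report
from .synthetic import SimConfig, simulate_experiment
from .water_use import compute_wui, daily_water_use, percent_fc_series

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "rank_genotypes"]

log = logging.getLogger("phenogrowth")


@dataclass
class PipelineConfig:
    # either a simulate block or paths to the four input CSVs
    simulate: SimConfig | None = None
    design_path: str | None = None
    features_path: str | None = None
    watering_path: str | None = None
    biomass_path: str | None = None

    resample: ResampleSpec = field(default_factory=ResampleSpec)
    families: tuple = tuple(f.value for f in ALL_FAMILIES)
    growth_windows: tuple = DEFAULT_WINDOWS
    spline_df: float | None = None
    h2_trait: str = "WUI_RGR"
    h2_window: tuple = (0, 21)
    h2_day_step: int = 3  # thin DAT levels inside the H2 window
    alpha: float = 0.05
    out_dir: str = "phenogrowth_out"
    seed: int = 0

    def __post_init__(self):
        if self.simulate is None and not (
            self.design_path
            and self.features_path
            and self.watering_path
            and self.biomass_path
        ):
            raise ValueError(
                "config needs either a simulate block or all four input paths"
            )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            raw = tomllib.loads(path.read_text())
        else:
            raw = json.loads(path.read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if raw.get("simulate") is not None:
            raw["simulate"] = SimConfig(**raw["simulate"])
        if raw.get("resample") is not None and not isinstance(
            raw["resample"], ResampleSpec
        ):
            raw["resample"] = ResampleSpec(**raw["resample"])
        if "growth_windows" in raw:
            raw["growth_windows"] = tuple(tuple(w) for w in raw["growth_windows"])
        if "h2_window" in raw:
            raw["h2_window"] = tuple(raw["h2_window"])
        return cls(**raw)

    def hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir", None)  # identifies the analysis, not its destination
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    evaluation_summary: dict  # metric -> six-number summary records
    chosen_family: str
    chosen_tune: dict
    selection_rationale: str
    final_cv: dict
    genotype_rates: pd.DataFrame  # genotype means + letters per window/treatment
    wui_windowed: pd.DataFrame
    heritability: dict
    artifacts: dict  # stage -> written file path

    def payload(self) -> dict:
        """JSON-stable report content (used for determinism checks)."""
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "evaluation_summary": self.evaluation_summary,
            "chosen_family": self.chosen_family,
            "chosen_tune": {k: str(v) for k, v in self.chosen_tune.items()},
            "selection_rationale": self.selection_rationale,
            "final_cv": {
                k: v
                for k, v in self.final_cv.items()
                if k in ("cv_ss", "r2", "F", "p_value", "slope", "intercept")
            },
            "heritability": self.heritability,
            "genotype_rates": self.genotype_rates.round(10).to_dict("records"),
        }


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulate is not None:
        sim = dataclasses.replace(cfg.simulate, seed=cfg.seed)
        design, features, ledger, biomass, truth = simulate_experiment(sim)
        return design, features, ledger, biomass, truth
    design = core_io.read_design(cfg.design_path)
    features = core_io.read_feature_table(cfg.features_path)
    ledger = core_io.read_watering_ledger(cfg.watering_path, design)
    biomass = core_io.read_biomass_table(cfg.biomass_path, design)
    return design, features, ledger, biomass, None


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    def save(df: pd.DataFrame, name: str):
        p = out / name
        df.to_csv(p, index=False)
        artifacts[name] = str(p)
        return p

    log.info("stage inputs: loading / simulating experiment")
    design, features, ledger, biomass, truth = _load_inputs(cfg)
    save(design.to_frame(), "design.csv")
    save(features.data, "features.csv")
    save(ledger.data, "watering.csv")
    save(biomass.data, "biomass.csv")
    log.info(
        "stage inputs: %d plants, %d feature rows, %d ledger rows",
        len(design.plants),
        len(features.data),
        len(ledger.data),
    )

    log.info("stage fit-models: evaluating %d families", len(cfg.families))
    resample = dataclasses.replace(cfg.resample, seed=cfg.seed)
    evaluation = evaluate_models(features, biomass, resample, cfg.families)
    # The final model is fitted on harvest-day plants but must predict much
    # smaller plants on earlier days. Tree ensembles predict constants
    # outside their training hull (a day-0 seedling would be assigned the
    # smallest harvest-day biomass), so they stay in the comparison table
    # but are not eligible as the daily-prediction model.
    extrapolating = [
        f for f in evaluation.families if f not in (Family.RF, Family.GBM)
    ] or None
    spec = select_model(evaluation, candidates=extrapolating)
    summary = {
        m: evaluation.summary(m).round(6).reset_index(names="family").to_dict("records")
        for m in ("MAE", "RMSE", "R2")
    }
    for m in ("MAE", "RMSE", "R2"):
        save(
            evaluation.summary(m).reset_index(names="family"),
            f"table1_{m.lower()}.csv",
        )
    log.info(
        "stage fit-models: chose %s (%s)", spec.family.value, evaluation.rationale
    )

    X, y, cols = _harvest_design(features, biomass)
    final_cv = crossvalidate_final(spec, X, y, k=min(10, len(y)), seed=cfg.seed)
    save(final_cv["predictions"], "final_cv_predictions.csv")

    fitted = fit_model(spec, X, y, feature_names=cols, seed=cfg.seed)
    pfb = predict_biomass(fitted, features)
    save(pfb, "pfb.csv")
    log.info("stage predict: %d PFB rows (%d clipped)", len(pfb), pfb["clipped"].sum())

    log.info("stage growth: smoothing %d trajectories", pfb["plant_id"].nunique())
    rates, smooth = compute_growth(pfb, cfg.growth_windows, df=cfg.spline_df)
    save(rates, "growth.csv")
    save(smooth, "growth_smoothed.csv")

    log.info("stage wui: water bookkeeping")
    water = daily_water_use(ledger)
    save(water.data, "water_use.csv")
    if cfg.simulate is not None:
        fc = percent_fc_series(ledger, cfg.simulate.field_capacity_g)
        save(fc, "percent_fc.csv")
    wui_daily, wui_win = compute_wui(pfb, rates, water)
    save(wui_daily, "wui_daily.csv")
    save(wui_win, "wui_windowed.csv")

    meta = design.to_frame()
    wui_meta = wui_win.merge(meta, on="plant_id")

    log.info("stage heritability: trait %s", cfg.h2_trait)
    heritability = _heritability_stage(cfg, wui_daily, smooth, water, meta)
    (out / "h2.json").write_text(json.dumps(heritability, indent=2))
    artifacts["h2.json"] = str(out / "h2.json")

    log.info("stage compare: Duncan letters per window x treatment")
    geno = _genotype_comparison(cfg, wui_meta)
    save(geno, "genotype_comparison.csv")

    report = RunReport(
        config_hash=cfg.hash(),
        seed=cfg.seed,
        evaluation_summary=summary,
        chosen_family=spec.family.value,
        chosen_tune=spec.hyperparams,
        selection_rationale=evaluation.rationale,
        final_cv=final_cv,
        genotype_rates=geno,
        wui_windowed=wui_win,
        heritability=heritability,
        artifacts=artifacts,
    )
    (out / "report.json").write_text(json.dumps(report.payload(), indent=2))
    return report


def _daily_trait(cfg, wui_daily, smooth, water):
    """Derived-trait values inside the H2 window, one per thinned DAT level.

    WUI_AGR / WUI_RGR at level d use the smoothed growth rate over the
    window from stress onset (the window's lower bound) to d, divided by the
    water used in that window — cumulative windows keep the rates positive
    and stable; WUI_BM is biomass over cumulative water on day d.
    """
    lo, hi = cfg.h2_window
    days = sorted(smooth["day"].unique())
    days = [d for d in days if lo <= d <= hi][:: max(1, cfg.h2_day_step)]
    if cfg.h2_trait == "WUI_BM":
        df = wui_daily[wui_daily["day"].isin(days)][["plant_id", "day", "WUI_BM"]]
        return df.rename(columns={"WUI_BM": "value"})
    sm = smooth.pivot(index="plant_id", columns="day", values="pfb_smooth")
    wu = water.data.pivot(index="pot_id", columns="day", values="wu_ml")
    # anchor at the first level where nearly all plants sit clear of the
    # prediction clipping floor; floor-level values are censored, not data
    floor = 2.0 * 0.01
    d0 = days[0]
    for d in days[:-1]:
        if d in sm.columns and (sm[d] > floor).mean() >= 0.9:
            d0 = d
            break
    rows = []
    for pid in sm.index:
        for d1 in days[1:]:
            if d1 <= d0:
                continue
            if d0 not in sm.columns or d1 not in sm.columns or pid not in wu.index:
                continue
            p0, p1 = sm.loc[pid, d0], sm.loc[pid, d1]
            span = [c for c in wu.columns if d0 < c <= d1]
            w = float(wu.loc[pid, span].sum())
            if not (np.isfinite(p0) and np.isfinite(p1)) or w <= 0:
                continue
            if p0 <= floor or p1 <= floor:
                continue
            if cfg.h2_trait == "WUI_AGR":
                val = (p1 - p0) / (d1 - d0) / w
            else:  # WUI_RGR
                val = (
                    (np.log(max(p1, 1e-6)) - np.log(max(p0, 1e-6))) / (d1 - d0) / w
                )
            rows.append({"plant_id": pid, "day": d1, "value": val})
    return pd.DataFrame(rows)


def _heritability_stage(cfg, wui_daily, smooth, water, meta) -> dict:
    trait = _daily_trait(cfg, wui_daily, smooth, water).merge(meta, on="plant_id")
    trait = trait[["genotype", "treatment", "day", "replicate", "value"]]
    # normality-driven log transform: index traits are multiplicative
    # across days, so raw-scale residuals are typically non-normal. A few
    # marginally negative values (spline wiggle on plateaued plants) are
    # absorbed by a scale-aware offset.
    transformed = False
    from scipy import stats as _stats

    import statsmodels.formula.api as _smf

    probe = _smf.ols("value ~ C(treatment) + C(day)", data=trait).fit()
    n_resid = len(probe.resid)
    sw_p = float(_stats.shapiro(probe.resid).pvalue) if n_resid <= 5000 else 0.0
    if sw_p < cfg.alpha:
        v = trait["value"]
        pos = v[v > 0]
        if len(pos) >= 0.9 * len(v) and len(pos) > 0:
            off = 0.0 if v.min() > 0 else float(-v.min() + np.percentile(pos, 1))
            trait = trait.assign(value=np.log(v + off))
            transformed = True
    rep = heritability_report(trait, trait_name=cfg.h2_trait)
    out = rep.to_dict()
    out["log_transformed"] = transformed
    return out


def _genotype_comparison(cfg, wui_meta: pd.DataFrame) -> pd.DataFrame:
    """Genotype means + Duncan letters for AGR, RGR and WUI per window and
    treatment."""
    out = []
    for (window, treatment), grp in wui_meta.groupby(["window", "treatment"]):
        for trait in ("AGR", "RGR", "WUI_AGR", "WUI_RGR"):
            vals = grp.dropna(subset=[trait])
            if vals["genotype"].nunique() < 2:
                continue
            counts = vals.groupby("genotype")[trait].count()
            if counts.min() < 2:
                continue
            letters = duncan_mrt(vals[trait], vals["genotype"], alpha=cfg.alpha)
            letters["window"] = window
            letters["treatment"] = treatment
            letters["trait"] = trait
            out.append(
                letters.rename(columns={"group": "genotype"})[
                    ["window", "treatment", "trait", "genotype", "mean", "n", "letters"]
                ]
            )
    return pd.concat(out, ignore_index=True)


def rank_genotypes(
    report: RunReport, trait: str, treatment: str, window: str | None = None
) -> pd.DataFrame:
    """Genotypes ordered by trait mean under a treatment, letters attached.

    Ties in means break stably by genotype id.
    """
    geno = report.genotype_rates
    sel = geno[(geno["trait"] == trait) & (geno["treatment"] == treatment)]
    if window is not None:
        sel = sel[sel["window"] == window]
    elif sel["window"].nunique() > 1:
        sel = sel[sel["window"] == sorted(sel["window"].unique())[0]]
    if sel.empty:
        raise KeyError(
            f"trait {trait!r} under treatment {treatment!r} not in report"
        )
    sel = sel.sort_values(
        ["mean", "genotype"], ascending=[False, True], kind="mergesort"
    )
    return sel.reset_index(drop=True)
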