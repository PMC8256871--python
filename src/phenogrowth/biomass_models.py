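"""Biomass prediction models: metrics, resampled evaluation, selection.

Eight regression families are compared for predicting harvest-day fresh
biomass from the geometry-only image features: linear model (LM), stepwise
linear (SM), principal-component regression (PC), partial least squares
(PLS), elastic net, random forest (RF), gradient boosting (GBM), and
multivariate adaptive regression splines (MARS). Each family is tuned and
scored on the same resamples (repeated k-fold by default, bootstrap
optionally); per-resample MAE / RMSE / R^2 distributions are summarized as
six-number statistics, and the final family is chosen by mean RMSE with a
one-standard-error parsimony rule that prefers fewer components.

Metrics: MAE = mean|actual - predicted|, MSE = mean squared error,
RMSE = sqrt(MSE), R^2 = 1 - SSres/SStot. Per-resample R^2 is recorded as the
squared Pearson correlation between held-out observed and predicted values,
which keeps it in [0, 1]; the 1 - SSres/SStot form is stored alongside.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.model_selection import KFold, RepeatedKFold

from .core_io import BiomassTable, FeatureTable, SchemaError

__all__ = [
    "Family",
    "ModelSpec",
    "ResampleSpec",
    "ModelEvaluation",
    "FittedModel",
    "compute_metrics",
    "fit_model",
    "evaluate_models",
    "select_model",
    "crossvalidate_final",
    "predict_biomass",
]


class Family(str, enum.Enum):
    LM = "LM"
    SM = "SM"
    PC = "PC"
    PLS = "PLS"
    ELASTICNET = "ELASTICNET"
    RF = "RF"
    GBM = "GBM"
    MARS = "MARS"


ALL_FAMILIES = tuple(Family)


def compute_metrics(actual, predicted) -> dict:
    """MAE / MSE / RMSE / R2 for a pair of equal-length numeric vectors."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("actual and predicted must be equal-length vectors (n >= 2)")
    if not (np.isfinite(a).all() and np.isfinite(p).all()):
        raise ValueError("non-finite values in metric inputs")
    resid = a - p
    mae = float(np.mean(np.abs(resid)))
    mse = float(np.mean(resid**2))
    rmse = float(np.sqrt(mse))
    sstot = float(np.sum((a - a.mean()) ** 2))
    if sstot == 0.0:
        r2 = float("nan")  # zero-variance actual: R^2 undefined
        r2_corr = float("nan")
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / sstot
        sp = np.std(p)
        r2_corr = float(np.corrcoef(a, p)[0, 1] ** 2) if sp > 0 else 0.0
    return {"MAE": mae, "MSE": mse, "RMSE": rmse, "R2": r2, "R2_corr": r2_corr}


# ---------------------------------------------------------------------------
# Preprocessing: leak-free mean imputation + centering/scaling, fit on the
# training split only.
# ---------------------------------------------------------------------------


class _Preproc:
    def fit(self, X: np.ndarray) -> "_Preproc":
        self.means_ = np.nanmean(X, axis=0)
        self.means_ = np.where(np.isfinite(self.means_), self.means_, 0.0)
        Ximp = self._impute(X)
        self.center_ = Ximp.mean(axis=0)
        sd = Ximp.std(axis=0, ddof=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def _impute(self, X):
        X = np.asarray(X, dtype=float).copy()
        nan = np.isnan(X)
        if nan.any():
            X[nan] = np.take(self.means_, np.where(nan)[1])
        return X

    def transform(self, X):
        return (self._impute(X) - self.center_) / self.scale_


# ---------------------------------------------------------------------------
# Hand-rolled families: stepwise AIC linear model, and MARS (forward hinge
# growth + backward pruning by generalized cross-validation).
# ---------------------------------------------------------------------------


class _Stepwise:
    """Forward-backward variable selection on a linear model by AIC."""

    def __init__(self, max_sweeps: int = 60):
        self.max_sweeps = max_sweeps

    @staticmethod
    def _aic(X, y, cols):
        n = len(y)
        Z = np.column_stack([np.ones(n)] + [X[:, j] for j in cols])
        coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
        rss = float(np.sum((y - Z @ coef) ** 2))
        rss = max(rss, 1e-300)
        return n * np.log(rss / n) + 2 * (len(cols) + 1), coef

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        p = X.shape[1]
        included: list[int] = []
        best_aic, self.coef_ = self._aic(X, y, included)
        for _ in range(self.max_sweeps):
            moves = []
            for j in range(p):
                cand = (
                    included + [j] if j not in included
                    else [c for c in included if c != j]
                )
                aic, coef = self._aic(X, y, cand)
                moves.append((aic, cand, coef))
            aic, cand, coef = min(moves, key=lambda m: m[0])
            if aic < best_aic - 1e-9:
                best_aic, included, self.coef_ = aic, cand, coef
            else:
                break
        self.included_ = included
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        Z = np.column_stack(
            [np.ones(len(X))] + [X[:, j] for j in self.included_]
        )
        return Z @ self.coef_

    @property
    def n_terms(self) -> int:
        return len(self.included_)


class _MARS:
    """Additive MARS: paired hinge bases max(0, x-t)/max(0, t-x), forward
    growth to ``max_terms`` basis functions, then backward pruning by GCV
    with the classic smoothing penalty."""

    def __init__(self, max_terms: int = 21, n_knots: int = 10, penalty: float = 3.0):
        self.max_terms = max_terms
        self.n_knots = n_knots
        self.penalty = penalty

    @staticmethod
    def _hinges(x, t):
        return np.maximum(0.0, x - t), np.maximum(0.0, t - x)

    def _gcv(self, rss, n, m):
        c = m + self.penalty * (m - 1) / 2.0
        denom = (1.0 - c / n) ** 2
        return np.inf if denom <= 0 else rss / n / denom

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        qs = np.linspace(0.05, 0.95, self.n_knots)
        knots = [np.unique(np.quantile(X[:, j], qs)) for j in range(p)]

        basis_desc: list[tuple] = [("intercept",)]
        used: set[tuple] = set()
        B = np.ones((n, 1))
        yty = float(y @ y)
        rss = float(np.sum((y - y.mean()) ** 2)) + 1e-12

        def _cand_rss(G, By, h1, h2):
            # RSS of [B, h1, h2] via bordered normal equations
            u1, u2 = B.T @ h1, B.T @ h2
            M = np.empty((G.shape[0] + 2, G.shape[0] + 2))
            m = G.shape[0]
            M[:m, :m] = G
            M[:m, m], M[m, :m] = u1, u1
            M[:m, m + 1], M[m + 1, :m] = u2, u2
            M[m, m] = h1 @ h1
            M[m + 1, m + 1] = h2 @ h2
            M[m, m + 1] = M[m + 1, m] = h1 @ h2
            rhs = np.concatenate([By, [h1 @ y, h2 @ y]])
            M[np.diag_indices_from(M)] += 1e-10  # rank-safe ridge
            c = np.linalg.solve(M, rhs)
            return yty - float(c @ rhs)

        while B.shape[1] + 2 <= self.max_terms:
            G, By = B.T @ B, B.T @ y
            best = None
            for j in range(p):
                for t in knots[j]:
                    if (j, t) in used:
                        continue
                    h1, h2 = self._hinges(X[:, j], t)
                    r = _cand_rss(G, By, h1, h2)
                    if best is None or r < best[0]:
                        best = (r, j, t)
            if best is None or best[0] > rss - 1e-12:
                break
            rss, j, t = best
            used.add((j, t))
            h1, h2 = self._hinges(X[:, j], t)
            basis_desc += [("hinge+", j, t), ("hinge-", j, t)]
            B = np.column_stack([B, h1, h2])

        # backward pruning by GCV
        active = list(range(B.shape[1]))
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        rss = float(np.sum((y - B @ coef) ** 2))
        best_subset, best_gcv = list(active), self._gcv(rss, n, len(active))
        while len(active) > 1:
            trial = None
            for drop in active[1:]:  # never drop the intercept
                cols = [c for c in active if c != drop]
                c, *_ = np.linalg.lstsq(B[:, cols], y, rcond=None)
                r = float(np.sum((y - B[:, cols] @ c) ** 2))
                if trial is None or r < trial[0]:
                    trial = (r, cols)
            active = trial[1]
            g = self._gcv(trial[0], n, len(active))
            if g < best_gcv:
                best_gcv, best_subset = g, list(active)
        self.basis_ = [basis_desc[i] for i in best_subset]
        Bb = B[:, best_subset]
        self.coef_, *_ = np.linalg.lstsq(Bb, y, rcond=None)
        return self

    def _design(self, X):
        X = np.asarray(X, dtype=float)
        cols = []
        for b in self.basis_:
            if b[0] == "intercept":
                cols.append(np.ones(len(X)))
            elif b[0] == "hinge+":
                cols.append(np.maximum(0.0, X[:, b[1]] - b[2]))
            else:
                cols.append(np.maximum(0.0, b[2] - X[:, b[1]]))
        return np.column_stack(cols)

    def predict(self, X):
        return self._design(X) @ self.coef_

    @property
    def n_terms(self) -> int:
        return len(self.basis_)


# ---------------------------------------------------------------------------
# Family construction and tuning grids.
# ---------------------------------------------------------------------------


def default_grid(family: Family, n: int, p: int) -> list[dict]:
    max_comp = max(1, min(20, p, n - 2))
    if family in (Family.PC, Family.PLS):
        return [{"n_components": k} for k in range(1, max_comp + 1)]
    if family is Family.ELASTICNET:
        return [
            {"l1_ratio": l1, "alpha": a}
            for l1 in np.round(np.arange(0.1, 1.01, 0.1), 2)
            for a in np.logspace(-3, 1, 10)
        ]
    if family is Family.RF:
        return [
            {"n_estimators": 500, "max_features": mf}
            for mf in ("sqrt", 0.33)
        ]
    if family is Family.GBM:
        return [
            {"max_depth": d, "n_estimators": ne, "learning_rate": 0.1}
            for d in (1, 2, 3)
            for ne in (100, 200, 300, 400, 500)
        ]
    if family is Family.MARS:
        return [{"max_terms": 21}]
    return [{}]  # LM, SM


@dataclass
class ModelSpec:
    family: Family
    tuning_grid: list[dict] = field(default_factory=list)
    hyperparams: dict = field(default_factory=dict)  # chosen point, if any

    def __post_init__(self):
        if isinstance(self.family, str):
            self.family = Family(self.family)


@dataclass
class ResampleSpec:
    scheme: str = "repeated_kfold"  # or "bootstrap"
    k: int = 10
    repeats: int = 5
    n_boot: int = 25
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in ("repeated_kfold", "bootstrap"):
            raise ValueError("scheme must be repeated_kfold or bootstrap")
        if self.k < 2 or self.repeats < 1 or self.n_boot < 1:
            raise ValueError("need k >= 2, repeats >= 1, n_boot >= 1")

    def splits(self, n: int) -> list[tuple[np.ndarray, np.ndarray]]:
        if self.scheme == "repeated_kfold":
            if n < self.k:
                raise ValueError(f"fewer samples ({n}) than folds ({self.k})")
            rkf = RepeatedKFold(
                n_splits=self.k, n_repeats=self.repeats, random_state=self.seed
            )
            return [(tr, te) for tr, te in rkf.split(np.arange(n))]
        rng = np.random.default_rng(self.seed)
        out = []
        while len(out) < self.n_boot:
            tr = rng.integers(0, n, size=n)
            te = np.setdiff1d(np.arange(n), tr)
            if len(te) >= 2:  # need a scorable out-of-bag set
                out.append((tr, te))
        return out


@dataclass
class FittedModel:
    family: Family
    hyperparams: dict
    feature_names: list[str]
    preproc: _Preproc
    model: object
    complexity: float
    rank_deficient: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.model.predict(self.preproc.transform(X))).ravel()


def _complexity(family: Family, model, p: int, hp: dict) -> float:
    if family in (Family.PC, Family.PLS):
        return float(hp.get("n_components", p))
    if family is Family.LM:
        return float(p)
    if family is Family.SM:
        return float(model.n_terms)
    if family is Family.ELASTICNET:
        return float(np.sum(np.abs(model.coef_) > 1e-10))
    if family is Family.MARS:
        return float(model.n_terms)
    return float(10 * p)  # ensemble families: never preferred on parsimony


def _fit_family(family: Family, Xs: np.ndarray, y: np.ndarray, hp: dict, seed: int):
    """Fit one family on already-preprocessed (imputed, scaled) data."""
    if family is Family.LM:
        m = LinearRegression().fit(Xs, y)
        return m, m.rank_ < Xs.shape[1]
    if family is Family.SM:
        return _Stepwise().fit(Xs, y), False
    if family is Family.PC:
        k = min(hp["n_components"], Xs.shape[0] - 1, Xs.shape[1])
        pca = PCA(n_components=k, random_state=seed).fit(Xs)
        lr = LinearRegression().fit(pca.transform(Xs), y)

        class _PCR:
            def predict(self, X, _pca=pca, _lr=lr):
                return _lr.predict(_pca.transform(X))

        return _PCR(), False
    if family is Family.PLS:
        k = min(hp["n_components"], Xs.shape[0] - 1, Xs.shape[1])
        m = PLSRegression(n_components=k, scale=False).fit(Xs, y.reshape(-1, 1))
        return m, False
    if family is Family.ELASTICNET:
        import warnings as _w

        from sklearn.exceptions import ConvergenceWarning

        with _w.catch_warnings():
            _w.simplefilter("ignore", ConvergenceWarning)
            m = ElasticNet(
                alpha=hp["alpha"], l1_ratio=hp["l1_ratio"], max_iter=5000
            ).fit(Xs, y)
        return m, False
    if family is Family.RF:
        m = RandomForestRegressor(
            n_estimators=hp["n_estimators"],
            max_features=hp["max_features"],
            random_state=seed,
            n_jobs=1,
        ).fit(Xs, y)
        return m, False
    if family is Family.GBM:
        m = GradientBoostingRegressor(
            max_depth=hp["max_depth"],
            n_estimators=hp["n_estimators"],
            learning_rate=hp["learning_rate"],
            random_state=seed,
        ).fit(Xs, y)
        return m, False
    if family is Family.MARS:
        return _MARS(max_terms=hp.get("max_terms", 21)).fit(Xs, y), False
    raise ValueError(f"unknown family {family}")


def fit_model(
    spec: ModelSpec,
    X,
    y,
    feature_names: list[str] | None = None,
    seed: int = 0,
) -> FittedModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 5:
        raise ValueError("need n >= 5 observations to fit")
    names = feature_names or [f"x{j}" for j in range(X.shape[1])]
    hp = spec.hyperparams or (
        default_grid(spec.family, *X.shape)[0] if spec.family in
        (Family.PC, Family.PLS, Family.ELASTICNET, Family.RF, Family.GBM, Family.MARS)
        else {}
    )
    pre = _Preproc().fit(X)
    Xs = pre.transform(X)
    model, deficient = _fit_family(spec.family, Xs, y, hp, seed)
    return FittedModel(
        family=spec.family,
        hyperparams=hp,
        feature_names=names,
        preproc=pre,
        model=model,
        complexity=_complexity(spec.family, model, X.shape[1], hp),
        rank_deficient=deficient,
    )


# ---------------------------------------------------------------------------
# Resampled evaluation (six-number summaries) and model selection.
# ---------------------------------------------------------------------------

SUMMARY_COLS = ("Min.", "1st Qu.", "Median", "Mean", "3rd Qu.", "Max.")


def _six_number(v: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {
        "Min.": float(np.min(v)),
        "1st Qu.": float(q1),
        "Median": float(med),
        "Mean": float(np.mean(v)),
        "3rd Qu.": float(q3),
        "Max.": float(np.max(v)),
    }


@dataclass
class ModelEvaluation:
    families: list[Family]
    resamples: dict  # family -> {"MAE": vec, "RMSE": vec, "R2": vec, "R2_ss": vec}
    best_tune: dict  # family -> hyperparameter dict
    complexity: dict  # family -> mean model complexity across resamples
    n_resamples: int
    feature_names: list[str]
    chosen: Family | None = None
    rationale: str = ""

    def summary(self, metric: str) -> pd.DataFrame:
        rows = {
            f.value: _six_number(np.asarray(self.resamples[f][metric]))
            for f in self.families
        }
        return pd.DataFrame(rows).T[list(SUMMARY_COLS)]


def _harvest_design(feature_table: FeatureTable, biomass: BiomassTable):
    bio = biomass.data
    day = int(bio["harvest_day"].mode().iloc[0])
    feats = feature_table.on_day(day)
    cols = feature_table.geometry_columns()
    merged = bio.merge(feats, on="plant_id", how="inner")
    if len(merged) < len(bio):
        missing = set(bio["plant_id"]) - set(merged["plant_id"])
        raise SchemaError(
            f"no harvest-day features for plants {sorted(missing)[:5]}"
        )
    X = merged[cols].to_numpy(dtype=float)
    y = merged["fresh_weight_g"].to_numpy(dtype=float)
    return X, y, cols


def evaluate_models(
    feature_table: FeatureTable,
    biomass: BiomassTable,
    resample: ResampleSpec | None = None,
    families=ALL_FAMILIES,
) -> ModelEvaluation:
    """Tune and score each family on shared resamples of the harvest-day data.

    For every family each tuning-grid point is fitted on each resample's
    training part (preprocessing refit inside the split) and scored on the
    held-out part; the grid point with the lowest mean RMSE is retained and
    its per-resample metric vectors are reported, caret-style.
    """
    resample = resample or ResampleSpec()
    X, y, cols = _harvest_design(feature_table, biomass)
    splits = resample.splits(len(y))
    families = [Family(f) for f in families]

    results, best_tunes, complexities = {}, {}, {}
    for fam in families:
        if fam is Family.GBM:
            per_grid = _evaluate_gbm(X, y, splits, resample.seed)
        else:
            per_grid = _evaluate_grid(fam, X, y, splits, resample.seed)
        best = min(per_grid, key=lambda g: g["RMSE"].mean())
        results[fam] = {k: best[k] for k in ("MAE", "RMSE", "R2", "R2_ss")}
        best_tunes[fam] = best["hp"]
        complexities[fam] = best["complexity"]

    return ModelEvaluation(
        families=families,
        resamples=results,
        best_tune=best_tunes,
        complexity=complexities,
        n_resamples=len(splits),
        feature_names=cols,
    )


def _evaluate_grid(fam, X, y, splits, seed):
    grid = default_grid(fam, len(y), X.shape[1])
    per_grid = []
    for hp in grid:
        mae, rmse, r2c, r2s, comp = [], [], [], [], []
        for si, (tr, te) in enumerate(splits):
            pre = _Preproc().fit(X[tr])
            model, _ = _fit_family(
                fam, pre.transform(X[tr]), y[tr], hp, seed=seed + si
            )
            pred = np.asarray(model.predict(pre.transform(X[te]))).ravel()
            m = compute_metrics(y[te], pred)
            mae.append(m["MAE"])
            rmse.append(m["RMSE"])
            r2c.append(m["R2_corr"])
            r2s.append(m["R2"])
            comp.append(_complexity(fam, model, X.shape[1], hp))
        per_grid.append(
            {
                "hp": hp,
                "MAE": np.array(mae),
                "RMSE": np.array(rmse),
                "R2": np.array(r2c),
                "R2_ss": np.array(r2s),
                "complexity": float(np.mean(comp)),
            }
        )
    return per_grid


def _evaluate_gbm(X, y, splits, seed):
    """GBM grid scored via staged predictions: one fit per depth at the
    maximum tree count covers every n_estimators candidate."""
    depths, tree_grid, lr = (1, 2, 3), (100, 200, 300, 400, 500), 0.1
    per_grid = []
    for depth in depths:
        acc = {ne: {"MAE": [], "RMSE": [], "R2": [], "R2_ss": []} for ne in tree_grid}
        for si, (tr, te) in enumerate(splits):
            pre = _Preproc().fit(X[tr])
            model = GradientBoostingRegressor(
                max_depth=depth,
                n_estimators=max(tree_grid),
                learning_rate=lr,
                random_state=seed + si,
            ).fit(pre.transform(X[tr]), y[tr])
            staged = list(model.staged_predict(pre.transform(X[te])))
            for ne in tree_grid:
                m = compute_metrics(y[te], staged[ne - 1])
                acc[ne]["MAE"].append(m["MAE"])
                acc[ne]["RMSE"].append(m["RMSE"])
                acc[ne]["R2"].append(m["R2_corr"])
                acc[ne]["R2_ss"].append(m["R2"])
        for ne in tree_grid:
            per_grid.append(
                {
                    "hp": {"max_depth": depth, "n_estimators": ne, "learning_rate": lr},
                    "MAE": np.array(acc[ne]["MAE"]),
                    "RMSE": np.array(acc[ne]["RMSE"]),
                    "R2": np.array(acc[ne]["R2"]),
                    "R2_ss": np.array(acc[ne]["R2_ss"]),
                    "complexity": float(10 * X.shape[1]),
                }
            )
    return per_grid


def select_model(
    evaluation: ModelEvaluation,
    parsimony: bool = True,
    candidates: list | None = None,
) -> ModelSpec:
    """Rank by (mean RMSE, mean MAE, -mean R2); within one resample standard
    error of the best RMSE, prefer the family with the fewest components.
    ``candidates`` optionally restricts the selectable families (the
    evaluation itself is untouched)."""
    fams = evaluation.families
    if candidates is not None:
        cand = {Family(f) for f in candidates}
        fams = [f for f in fams if f in cand]
        if not fams:
            raise ValueError("no evaluated family among the candidates")
    key = {
        f: (
            evaluation.resamples[f]["RMSE"].mean(),
            evaluation.resamples[f]["MAE"].mean(),
            -evaluation.resamples[f]["R2"].mean(),
        )
        for f in fams
    }
    ranked = sorted(fams, key=lambda f: key[f])
    best = ranked[0]
    rationale = f"lowest mean RMSE: {best.value} ({key[best][0]:.4g})"
    chosen = best
    if parsimony and len(fams) > 1:
        v = evaluation.resamples[best]["RMSE"]
        se = float(np.std(v, ddof=1) / np.sqrt(len(v)))
        cutoff = key[best][0] + se
        within = [f for f in fams if evaluation.resamples[f]["RMSE"].mean() <= cutoff]
        chosen = min(
            within, key=lambda f: (evaluation.complexity[f], key[f])
        )
        if chosen != best:
            rationale = (
                f"{chosen.value} within one SE ({se:.4g}) of best RMSE "
                f"({best.value}, {key[best][0]:.4g}) with lower complexity "
                f"({evaluation.complexity[chosen]:.1f} vs "
                f"{evaluation.complexity[best]:.1f})"
            )
    evaluation.chosen = chosen
    evaluation.rationale = rationale
    return ModelSpec(family=chosen, hyperparams=dict(evaluation.best_tune[chosen]))


def crossvalidate_final(
    spec: ModelSpec, X, y, k: int = 10, seed: int = 0
) -> dict:
    """Final k-fold cross-validation check of the chosen model: fold-wise
    held-out predictions, pooled CV residual sum of squares, and an F-test of
    the observed ~ predicted regression."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    pred = np.empty(n)
    fold = np.empty(n, dtype=int)
    fold_ss = []
    for i, (tr, te) in enumerate(kf.split(X)):
        pre = _Preproc().fit(X[tr])
        model, _ = _fit_family(
            spec.family, pre.transform(X[tr]), y[tr], spec.hyperparams, seed=seed + i
        )
        p = np.asarray(model.predict(pre.transform(X[te]))).ravel()
        pred[te] = p
        fold[te] = i
        fold_ss.append(float(np.sum((y[te] - p) ** 2)))
    lr = stats.linregress(pred, y)
    fstat = float(lr.rvalue**2 / max(1e-300, 1 - lr.rvalue**2) * (n - 2))
    return {
        "predictions": pd.DataFrame({"fold": fold, "observed": y, "predicted": pred}),
        "fold_ss": fold_ss,
        "cv_ss": float(np.sum(fold_ss)),
        "slope": float(lr.slope),
        "intercept": float(lr.intercept),
        "r2": float(lr.rvalue**2),
        "F": fstat,
        "p_value": float(lr.pvalue),
    }


def predict_biomass(
    model: FittedModel,
    feature_table: FeatureTable,
    floor_g: float = 0.01,
) -> pd.DataFrame:
    """Per (plant_id, day) predicted fresh biomass (PFB, grams).

    Negative raw predictions are clipped to ``floor_g`` and flagged.
    """
    missing = [c for c in model.feature_names if c not in feature_table.data.columns]
    if missing:
        raise SchemaError(f"feature table missing model predictors: {missing[:5]}")
    X = feature_table.data[model.feature_names].to_numpy(dtype=float)
    raw = model.predict(X)
    clipped = raw < floor_g
    out = feature_table.data[["plant_id", "day"]].copy()
    out["pfb_g"] = np.where(clipped, floor_g, raw)
    out["clipped"] = clipped
    return out
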