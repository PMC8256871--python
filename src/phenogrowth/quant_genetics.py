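"""Variance components, broad-sense heritability, ANOVA and Duncan's test.

The heritability model decomposes a derived trait observed over genotypes
(G), water treatments (T), days after treatment (DAT) and replicates into
variance components via REML: genotype is random (giving sigma_g^2 and
genotype BLUPs), replication and the G x T, G x DAT, G x T x DAT
interactions are random, and treatment/DAT enter as fixed factors. A
companion fit with genotype fixed yields genotype BLUEs. Three broad-sense
heritability estimators are computed:

    standard:  H^2 = sigma_g^2 / sigma_p^2
    Cullis:    H^2 = 1 - vdBLUP / (2 sigma_g^2)
    Piepho:    H^2 = sigma_g^2 / (sigma_g^2 + vdBLUE / 2)

where vdBLUP / vdBLUE are the mean variances of a difference of two genotypic
BLUPs / BLUEs. The phenotypic variance for the standard estimator follows
the mean-basis composition: each interaction component is divided by the
number of levels of the non-genotype factors it involves, and the residual
by the full replication multiplier.

REML is fitted by the profiled penalized-least-squares formulation of the
mixed-model equations (the lme4 device): variance ratios are optimized on
the log scale, and prediction-error (co)variances of BLUPs and BLUE
contrast variances come from the inverse coefficient matrix.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "MixedModelResult",
    "VarianceComponents",
    "HeritabilityReport",
    "fit_mixed_model",
    "fit_variance_components",
    "h2_standard",
    "h2_cullis",
    "h2_piepho",
    "heritability_report",
    "anova_glm",
    "duncan_mrt",
]

TRAIT_COLUMNS = ("genotype", "treatment", "day", "replicate", "value")


# ---------------------------------------------------------------------------
# Design-matrix construction
# ---------------------------------------------------------------------------


def _one_hot(codes: np.ndarray, q: int) -> np.ndarray:
    Z = np.zeros((len(codes), q))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def _term_matrix(df: pd.DataFrame, term: str) -> tuple[np.ndarray, list]:
    factors = term.split(":")
    keys = df[factors].astype(str).agg("|".join, axis=1)
    codes, levels = pd.factorize(keys, sort=True)
    return _one_hot(codes, len(levels)), list(levels)


def _fixed_matrix(df: pd.DataFrame, fixed_terms) -> np.ndarray:
    cols = [np.ones(len(df))]
    for term in fixed_terms:
        Z, levels = _term_matrix(df, term)
        cols.append(Z[:, 1:])  # drop-first coding
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Profiled REML
# ---------------------------------------------------------------------------


@dataclass
class MixedModelResult:
    sigma2: dict  # term -> variance component
    sigma2_resid: float
    blups: dict  # term -> pd.Series indexed by level
    pev: dict  # term -> PEV matrix of the BLUPs
    fixed_effects: np.ndarray
    fixed_cov: np.ndarray  # sampling covariance of fixed effects
    deviance: float
    converged: bool
    at_bound: list  # terms whose variance hit the zero bound


def _reml_deviance(loglam, XtX, XtZ, ZtZ, Xty, Zty, yty, n, p, sizes):
    lam = np.exp(np.clip(loglam, -30.0, 30.0))
    s = np.concatenate([np.full(q, np.sqrt(l)) for l, q in zip(lam, sizes)])
    # A = Z diag(s);  M = A'A + I
    M = (ZtZ * s[None, :]) * s[:, None]
    M[np.diag_indices_from(M)] += 1.0
    L = np.linalg.cholesky(M)
    term1 = 2.0 * np.sum(np.log(np.diag(L)))
    AtX = XtZ.T * s[:, None]
    Aty = Zty * s
    W = np.linalg.solve(L, np.column_stack([AtX, Aty[:, None]]))
    WX, wy = W[:, :-1], W[:, -1]
    RxtRx = XtX - WX.T @ WX
    Lx = np.linalg.cholesky(RxtRx)
    term2 = 2.0 * np.sum(np.log(np.diag(Lx)))
    # solve for fixed effects then random effects
    rhs_b = Xty - WX.T @ wy
    b = np.linalg.solve(Lx.T, np.linalg.solve(Lx, rhs_b))
    # u* solves (A'A + I) u* = A'(y - X b); penalized RSS = y'y - u*'A'y - b'X'y
    u_full = np.linalg.solve(L.T, np.linalg.solve(L, Aty - AtX @ b))
    r2 = float(yty - u_full @ Aty - b @ Xty)
    r2 = max(r2, 1e-300)
    dev = term1 + term2 + (n - p) * (1.0 + np.log(2.0 * np.pi * r2 / (n - p)))
    return dev, lam, b, u_full, r2, s


def fit_mixed_model(
    y: np.ndarray,
    X: np.ndarray,
    random_terms: dict,
    maxfev: int = 400,
) -> MixedModelResult:
    """REML fit of y = X b + sum_i Z_i u_i + e with u_i ~ N(0, sigma_i^2 I).

    ``random_terms`` maps term name -> (Z indicator matrix, level labels).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design is rank deficient")
    names = list(random_terms)
    Zs = [np.asarray(random_terms[t][0], dtype=float) for t in names]
    sizes = [Z.shape[1] for Z in Zs]
    Z = np.hstack(Zs)
    XtX, XtZ, ZtZ = X.T @ X, X.T @ Z, Z.T @ Z
    Xty, Zty, yty = X.T @ y, Z.T @ y, float(y @ y)

    def obj(loglam):
        try:
            return _reml_deviance(
                loglam, XtX, XtZ, ZtZ, Xty, Zty, yty, n, p, sizes
            )[0]
        except np.linalg.LinAlgError:
            return 1e12

    x0 = np.zeros(len(names))
    if len(names) == 1:
        res = optimize.minimize_scalar(
            lambda t: obj(np.array([t])), bounds=(-25.0, 15.0), method="bounded",
            options={"xatol": 1e-6},
        )
        xopt = np.array([res.x])
        converged = res.success
    else:
        res = optimize.minimize(
            obj,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxfev": maxfev},
        )
        xopt = res.x
        converged = bool(res.success or res.fun < obj(x0))
    dev, lam, b, u_full, r2, s = _reml_deviance(
        xopt, XtX, XtZ, ZtZ, Xty, Zty, yty, n, p, sizes
    )
    sigma2_e = r2 / (n - p)
    sigma2 = {t: float(l * sigma2_e) for t, l in zip(names, lam)}
    at_bound = [t for t, x in zip(names, np.atleast_1d(xopt)) if x < -20.0]

    # inverse coefficient matrix of the lambda-scaled mixed-model equations
    q = sum(sizes)
    M = (ZtZ * s[None, :]) * s[:, None]
    M[np.diag_indices_from(M)] += 1.0
    AtX = XtZ.T * s[:, None]
    C = np.block([[M, AtX], [AtX.T, XtX]])
    Cinv = np.linalg.inv(C)

    blups, pev = {}, {}
    offset = 0
    for t, Z_t, sz in zip(names, Zs, sizes):
        levels = random_terms[t][1]
        sl = slice(offset, offset + sz)
        u_t = s[sl] * u_full[sl]  # u = Lambda u*
        blups[t] = pd.Series(u_t, index=levels)
        pev[t] = (
            sigma2_e
            * (s[sl][:, None] * Cinv[sl, sl] * s[sl][None, :])
        )
        offset += sz
    fixed_cov = sigma2_e * Cinv[q:, q:]
    return MixedModelResult(
        sigma2=sigma2,
        sigma2_resid=float(sigma2_e),
        blups=blups,
        pev=pev,
        fixed_effects=b,
        fixed_cov=fixed_cov,
        deviance=float(dev),
        converged=converged,
        at_bound=at_bound,
    )


# ---------------------------------------------------------------------------
# Variance components + BLUP/BLUE machinery for heritability
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_resid: float
    components: dict  # all random-term variances, incl. genotype
    v_delta_blup: float
    v_delta_blue: float
    blups: pd.Series
    blues: pd.Series
    n_levels: dict  # factor -> number of levels (for mean-basis divisors)
    genotype_terms: dict  # interaction term -> variance (terms involving G)
    converged: bool


def _mean_pairwise_diff_var(cov: np.ndarray) -> float:
    q = cov.shape[0]
    d = np.diag(cov)
    total = 0.0
    for i, j in itertools.combinations(range(q), 2):
        total += d[i] + d[j] - 2.0 * cov[i, j]
    return total / (q * (q - 1) / 2.0)


def validate_trait_table(trait: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRAIT_COLUMNS if c not in trait.columns]
    if missing:
        raise ValueError(f"trait table missing columns {missing}")
    df = trait.dropna(subset=["value"]).copy()
    if not np.isfinite(df["value"]).all():
        raise ValueError("non-finite trait values")
    if df["genotype"].nunique() < 2:
        raise ValueError("need >= 2 genotypes")
    if df["replicate"].nunique() < 2:
        raise ValueError("need >= 2 replicates")
    return df


def _default_terms(df: pd.DataFrame):
    nT = df["treatment"].nunique()
    nD = df["day"].nunique()
    fixed = [t for t, n in (("treatment", nT), ("day", nD)) if n >= 2]
    random = []
    if df["replicate"].nunique() >= 2:
        random.append("replicate")
    random.append("genotype")
    if nT >= 2:
        random.append("genotype:treatment")
    if nD >= 2:
        random.append("genotype:day")
    if nT >= 2 and nD >= 2:
        random.append("genotype:treatment:day")
    return fixed, random


def fit_variance_components(
    trait: pd.DataFrame,
    random_terms: list | None = None,
    fixed_terms: list | None = None,
    maxfev: int = 400,
) -> VarianceComponents:
    """REML variance components plus genotype BLUPs, BLUEs and the mean
    pairwise difference variances needed by the Cullis and Piepho
    heritability estimators."""
    df = validate_trait_table(trait)
    auto_fixed, auto_random = _default_terms(df)
    fixed = list(fixed_terms) if fixed_terms is not None else auto_fixed
    random = list(random_terms) if random_terms is not None else auto_random
    if "genotype" not in random:
        raise ValueError("random terms must include 'genotype'")

    y = df["value"].to_numpy(dtype=float)
    X = _fixed_matrix(df, fixed)
    rts = {t: _term_matrix(df, t) for t in random}
    fit = fit_mixed_model(y, X, rts, maxfev=maxfev)
    vd_blup = _mean_pairwise_diff_var(fit.pev["genotype"])

    # companion fit: genotype fixed (means model), other random terms kept
    Zg, g_levels = _term_matrix(df, "genotype")
    X_blue = np.column_stack([Zg] + [
        _term_matrix(df, t)[0][:, 1:] for t in fixed
    ])
    random_blue = {t: rts[t] for t in random if not t.startswith("genotype")}
    ng = len(g_levels)
    if random_blue:
        fit_blue = fit_mixed_model(y, X_blue, random_blue, maxfev=maxfev)
        blues = pd.Series(fit_blue.fixed_effects[:ng], index=g_levels)
        cov_g = fit_blue.fixed_cov[:ng, :ng]
    else:
        # pure fixed-effects model: ordinary least squares
        coef, _, rank, _ = np.linalg.lstsq(X_blue, y, rcond=None)
        resid = y - X_blue @ coef
        dfe = len(y) - X_blue.shape[1]
        s2 = float(resid @ resid) / dfe
        xtx_inv = np.linalg.inv(X_blue.T @ X_blue)
        blues = pd.Series(coef[:ng], index=g_levels)
        cov_g = s2 * xtx_inv[:ng, :ng]
    vd_blue = _mean_pairwise_diff_var(cov_g)

    n_levels = {
        "treatment": int(df["treatment"].nunique()),
        "day": int(df["day"].nunique()),
        "replicate": int(df["replicate"].nunique()),
    }
    g_terms = {
        t: v
        for t, v in fit.sigma2.items()
        if "genotype" in t.split(":") and t != "genotype"
    }
    return VarianceComponents(
        sigma2_g=fit.sigma2["genotype"],
        sigma2_resid=fit.sigma2_resid,
        components=fit.sigma2,
        v_delta_blup=float(vd_blup),
        v_delta_blue=float(vd_blue),
        blups=fit.blups["genotype"],
        blues=blues,
        n_levels=n_levels,
        genotype_terms=g_terms,
        converged=fit.converged,
    )


def h2_standard(vc: VarianceComponents) -> float:
    """sigma_g^2 over the mean-basis phenotypic variance: each G-interaction
    divided by the levels of its non-genotype factors, residual divided by
    the full replication multiplier."""
    sigma_p = vc.sigma2_g
    for term, v in vc.genotype_terms.items():
        divisor = 1
        for f in term.split(":"):
            if f != "genotype":
                divisor *= vc.n_levels.get(f, 1)
        sigma_p += v / divisor
    resid_div = (
        vc.n_levels.get("treatment", 1)
        * vc.n_levels.get("day", 1)
        * vc.n_levels.get("replicate", 1)
    )
    sigma_p += vc.sigma2_resid / resid_div
    if sigma_p <= 0:
        raise ZeroDivisionError("phenotypic variance is zero")
    return float(np.clip(vc.sigma2_g / sigma_p, 0.0, 1.0))


def h2_cullis(sigma2_g: float, v_delta_blup: float) -> float:
    """1 - vdBLUP / (2 sigma_g^2), clamped to [0, 1]; defined as 0 when
    sigma_g^2 = 0."""
    if sigma2_g <= 0:
        return 0.0
    return float(np.clip(1.0 - v_delta_blup / (2.0 * sigma2_g), 0.0, 1.0))


def h2_piepho(sigma2_g: float, v_delta_blue: float) -> float:
    """sigma_g^2 / (sigma_g^2 + vdBLUE / 2)."""
    denom = sigma2_g + v_delta_blue / 2.0
    if denom <= 0:
        raise ZeroDivisionError("sigma_g^2 and vdBLUE both zero")
    return float(np.clip(sigma2_g / denom, 0.0, 1.0))


@dataclass
class HeritabilityReport:
    trait_name: str
    h2_standard: float
    h2_cullis: float
    h2_piepho: float
    variance_components: VarianceComponents
    model_record: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "trait": self.trait_name,
            "H2_standard": self.h2_standard,
            "H2_cullis": self.h2_cullis,
            "H2_piepho": self.h2_piepho,
            "sigma2_g": self.variance_components.sigma2_g,
            "sigma2_resid": self.variance_components.sigma2_resid,
            "components": self.variance_components.components,
            "v_delta_blup": self.variance_components.v_delta_blup,
            "v_delta_blue": self.variance_components.v_delta_blue,
            "converged": self.variance_components.converged,
            "model": self.model_record,
        }


def heritability_report(
    trait: pd.DataFrame,
    trait_name: str = "trait",
    random_terms: list | None = None,
    fixed_terms: list | None = None,
    maxfev: int = 400,
) -> HeritabilityReport:
    vc = fit_variance_components(
        trait, random_terms=random_terms, fixed_terms=fixed_terms, maxfev=maxfev
    )
    return HeritabilityReport(
        trait_name=trait_name,
        h2_standard=h2_standard(vc),
        h2_cullis=h2_cullis(vc.sigma2_g, vc.v_delta_blup),
        h2_piepho=h2_piepho(vc.sigma2_g, vc.v_delta_blue),
        variance_components=vc,
        model_record={
            "random": random_terms or "auto",
            "fixed": fixed_terms or "auto",
        },
    )


# ---------------------------------------------------------------------------
# ANOVA + Duncan multiple range test
# ---------------------------------------------------------------------------


def anova_glm(
    data: pd.DataFrame,
    formula: str,
    alpha: float = 0.05,
    log_offset: float | None = None,
) -> dict:
    """Type-II ANOVA via a general linear model, with a Shapiro-Wilk
    normality check on residuals triggering a log(x + offset) refit."""
    response = formula.split("~")[0].strip()
    y = data[response].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError("degenerate trait: zero variance")
    fit = smf.ols(formula, data=data).fit()
    if fit.df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    sw_p = float(stats.shapiro(fit.resid).pvalue) if len(fit.resid) <= 5000 else 1.0
    transformed = False
    if sw_p < alpha:
        off = log_offset
        if off is None:
            off = 0.0 if y.min() > 0 else float(-y.min() + 1.0)
        tdata = data.copy()
        tdata[response] = np.log(tdata[response] + off)
        fit = smf.ols(formula, data=tdata).fit()
        transformed = True
    table = sm.stats.anova_lm(fit, typ=2)
    return {
        "anova": table,
        "fit": fit,
        "shapiro_p": sw_p,
        "log_transformed": transformed,
        "mse": float(fit.mse_resid),
        "df_resid": int(fit.df_resid),
    }


def _duncan_significance(means, ns, mse, dfe, alpha):
    """Boolean matrix over sorted-descending means: True = significantly
    different under Duncan's protected ranges."""
    k = len(means)
    n_h = k / np.sum(1.0 / np.asarray(ns, dtype=float))
    order = np.argsort(means)[::-1]
    sorted_means = np.asarray(means)[order]
    sig = np.zeros((k, k), dtype=bool)
    # critical range per span r, with Duncan's protection level
    ranges = {}
    for r in range(2, k + 1):
        level = (1.0 - alpha) ** (r - 1)
        q = stats.studentized_range.ppf(level, r, dfe)
        ranges[r] = q * np.sqrt(mse / n_h)
    # widest spans first: a nonsignificant span protects everything inside
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            diff = sorted_means[i] - sorted_means[j]
            if diff > ranges[span]:
                sig[i, j] = sig[j, i] = True
    # containment: any pair inside a nonsignificant pair is nonsignificant
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if not sig[i, j]:
                sig[i : j + 1, i : j + 1] = False
    return sig, order, sorted_means, n_h


def _letters_from_sig(sig: np.ndarray) -> list[str]:
    """Compact letter display from a significance matrix on sorted means."""
    k = sig.shape[0]
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and not sig[i, j + 1]:
            j += 1
        intervals.append((i, j))
    # keep maximal intervals only
    maximal = [
        (a, b)
        for a, b in intervals
        if not any((c <= a and b <= d) and (c, d) != (a, b) for c, d in intervals)
    ]
    maximal = sorted(set(maximal))
    letters = ["" for _ in range(k)]
    for idx, (a, b) in enumerate(maximal):
        ch = chr(ord("a") + idx) if idx < 26 else f"z{idx}"
        for g in range(a, b + 1):
            letters[g] += ch
    return letters


def duncan_mrt(
    values,
    groups,
    alpha: float = 0.05,
    mse: float | None = None,
    df_error: int | None = None,
) -> pd.DataFrame:
    """Duncan multiple range test with a compact letter display.

    Groups sharing a letter are not significantly different at the given
    alpha. Unequal group sizes are handled with the harmonic mean (flagged
    via the n_harmonic column). When mse/df_error are not supplied they are
    taken from a one-way ANOVA of values on groups.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": groups})
    agg = df.groupby("group")["value"].agg(["mean", "count"])
    k = len(agg)
    if k < 2:
        agg["letters"] = "a"
        return agg.reset_index().rename(columns={"mean": "mean", "count": "n"})
    if mse is None or df_error is None:
        grand = df["value"].mean()
        ss_within = float(
            df.groupby("group")["value"].apply(lambda v: ((v - v.mean()) ** 2).sum()).sum()
        )
        df_error = len(df) - k
        if df_error <= 0:
            raise ValueError("no residual degrees of freedom for Duncan test")
        mse = ss_within / df_error
    sig, order, sorted_means, n_h = _duncan_significance(
        agg["mean"].to_numpy(), agg["count"].to_numpy(), mse, df_error, alpha
    )
    letters_sorted = _letters_from_sig(sig)
    out = agg.iloc[order].reset_index()
    out = out.rename(columns={"mean": "mean", "count": "n"})
    out["letters"] = letters_sorted
    out["n_harmonic"] = n_h
    return out
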