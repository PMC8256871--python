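import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenogrowth.quant_genetics import (
    VarianceComponents,
    anova_glm,
    duncan_mrt,
    fit_variance_components,
    h2_cullis,
    h2_piepho,
    h2_standard,
    heritability_report,
)


def one_way_trait(rng, n_geno=24, n_rep=3, sigma_g2=0.7, sigma_e2=0.9, mu=10.0):
    rows = []
    for gi in range(n_geno):
        g = rng.normal(0, np.sqrt(sigma_g2))
        for rep in range(1, n_rep + 1):
            rows.append(
                {
                    "genotype": f"G{gi:02d}",
                    "treatment": "well_watered",
                    "day": 5,
                    "replicate": rep,
                    "value": mu + g + rng.normal(0, np.sqrt(sigma_e2)),
                }
            )
    return pd.DataFrame(rows)


def factorial_trait(
    rng, n_geno=24, n_rep=3, n_trt=2, n_day=2, sigma_g2=0.7, sigma_e2=0.9, mu=10.0
):
    rows = []
    for gi in range(n_geno):
        g = rng.normal(0, np.sqrt(sigma_g2))
        for t in range(n_trt):
            for d in range(n_day):
                for rep in range(1, n_rep + 1):
                    rows.append(
                        {
                            "genotype": f"G{gi:02d}",
                            "treatment": f"T{t}",
                            "day": d,
                            "replicate": rep,
                            "value": mu + g + rng.normal(0, np.sqrt(sigma_e2)),
                        }
                    )
    return pd.DataFrame(rows)


class TestVarianceComponents:
    def test_single_genotype_precondition(self, rng):
        df = one_way_trait(rng, n_geno=1)
        with pytest.raises(ValueError, match="genotype"):
            fit_variance_components(df)

    def test_balanced_recovery_matches_anova_estimator(self, rng):
        """Balanced one-way REML equals the classic EMS estimator."""
        df = one_way_trait(rng, n_geno=30, n_rep=4)
        vc = fit_variance_components(df, random_terms=["genotype"])
        wide = df.pivot_table(index="genotype", columns="replicate", values="value")
        ms_between = wide.mean(axis=1).var(ddof=1) * 4
        ms_within = wide.var(axis=1, ddof=1).mean()
        sigma_g_anova = max(0.0, (ms_between - ms_within) / 4)
        assert vc.sigma2_g == pytest.approx(sigma_g_anova, rel=1e-3, abs=1e-6)
        assert vc.sigma2_resid == pytest.approx(ms_within, rel=1e-3)

    def test_null_genotype_variance_shrinks_to_zero(self):
        """With sigma_g2 = 0 and factorial replication the genotype variance
        estimate collapses well below the residual variance."""
        hits = 0
        n_sims = 20
        for s in range(n_sims):
            rng = np.random.default_rng(1000 + s)
            df = factorial_trait(rng, sigma_g2=0.0, sigma_e2=1.0)
            vc = fit_variance_components(df, random_terms=["genotype"])
            if vc.sigma2_g < 0.05 * vc.sigma2_resid:
                hits += 1
        assert hits >= 0.9 * n_sims

    def test_matches_lme4_reml_on_fixture(self, tmp_path):
        """Independent cross-check of the REML engine against R lme4."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable for the lme4 cross-check")
        rng = np.random.default_rng(42)
        df = one_way_trait(rng, n_geno=10, n_rep=3)
        vc = fit_variance_components(df, random_terms=["genotype"])
        csv = tmp_path / "trait.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            'suppressMessages(library(lme4));'
            f'd <- read.csv("{csv}");'
            "m <- lmer(value ~ (1|genotype), data=d, REML=TRUE);"
            "v <- as.data.frame(VarCorr(m));"
            'cat(v$vcov[1], v$vcov[2], sep="\\n")'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        g_lme4, e_lme4 = (float(x) for x in out.stdout.strip().split())
        assert vc.sigma2_g == pytest.approx(g_lme4, rel=1e-3, abs=1e-6)
        assert vc.sigma2_resid == pytest.approx(e_lme4, rel=1e-3)


def _vc(sigma_g2, resid, n_rep=1, **inter):
    return VarianceComponents(
        sigma2_g=sigma_g2,
        sigma2_resid=resid,
        components={"genotype": sigma_g2, **inter},
        v_delta_blup=0.0,
        v_delta_blue=0.0,
        blups=pd.Series(dtype=float),
        blues=pd.Series(dtype=float),
        n_levels={"treatment": 1, "day": 1, "replicate": n_rep},
        genotype_terms=inter,
        converged=True,
    )


class TestHeritabilityEstimators:
    def test_standard_arithmetic(self):
        # sigma_g2=3, residual 1 with single rep -> sigma_p2=4
        assert h2_standard(_vc(3.0, 1.0)) == pytest.approx(0.75)

    def test_standard_zero_genetic_variance(self):
        assert h2_standard(_vc(0.0, 1.0)) == 0.0

    def test_cullis_arithmetic_and_limits(self):
        assert h2_cullis(2.0, 1.0) == pytest.approx(0.75)
        assert h2_cullis(2.0, 0.0) == 1.0
        assert h2_cullis(0.0, 1.0) == 0.0

    def test_piepho_arithmetic_and_limits(self):
        assert h2_piepho(3.0, 2.0) == pytest.approx(0.75)
        assert h2_piepho(3.0, 1e-12) == pytest.approx(1.0)
        assert h2_piepho(0.0, 1.0) == 0.0
        with pytest.raises(ZeroDivisionError):
            h2_piepho(0.0, 0.0)

    def test_monotone_in_genetic_variance(self):
        vals = [h2_standard(_vc(s, 1.0)) for s in (0.1, 0.5, 1.0, 5.0)]
        assert vals == sorted(vals)

    def test_estimators_agree_on_balanced_design(self, rng):
        df = one_way_trait(rng, n_geno=24, n_rep=3)
        rep = heritability_report(df)
        assert abs(rep.h2_standard - rep.h2_cullis) < 0.05
        assert abs(rep.h2_standard - rep.h2_piepho) < 0.05

    def test_vanishing_residual_drives_h2_to_one(self, rng):
        df = one_way_trait(rng, sigma_g2=1.0, sigma_e2=1e-6)
        rep = heritability_report(df)
        assert rep.h2_standard > 0.99
        assert rep.h2_cullis > 0.99
        assert rep.h2_piepho > 0.99


class TestAnovaGlm:
    def test_strong_group_separation_detected(self, rng):
        df = pd.DataFrame(
            {
                "value": np.r_[rng.normal(0, 1, 40), rng.normal(5, 1, 40)],
                "grp": ["a"] * 40 + ["b"] * 40,
            }
        )
        out = anova_glm(df, "value ~ C(grp)")
        assert out["anova"]["PR(>F)"].iloc[0] < 1e-6

    def test_constant_trait_rejected(self):
        df = pd.DataFrame({"value": [1.0] * 10, "grp": list("ab") * 5})
        with pytest.raises(ValueError, match="zero variance"):
            anova_glm(df, "value ~ C(grp)")

    def test_non_normal_residuals_trigger_log_refit(self, rng):
        df = pd.DataFrame(
            {
                "value": rng.lognormal(0.0, 1.5, 200),
                "grp": list("ab") * 100,
            }
        )
        out = anova_glm(df, "value ~ C(grp)")
        assert out["shapiro_p"] < 0.05
        assert out["log_transformed"]


# ---------------------------------------------------------------------------
# Duncan multiple range test
# ---------------------------------------------------------------------------


def brute_force_duncan_partition(means, ns, mse, dfe, alpha):
    """Independent all-pairs oracle: protected Duncan ranges, then letter
    groups as maximal intervals of mutually nonsignificant sorted means."""
    order = np.argsort(means)[::-1]
    sm = np.asarray(means)[order]
    k = len(sm)
    n_h = k / np.sum(1.0 / np.asarray(ns, dtype=float))
    different = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            r = j - i + 1
            q = stats.studentized_range.ppf((1 - alpha) ** (r - 1), r, dfe)
            different[i, j] = different[j, i] = (
                sm[i] - sm[j] > q * np.sqrt(mse / n_h)
            )
    # protection: pairs nested in a nonsignificant span are nonsignificant
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if not different[i, j]:
                different[i : j + 1, i : j + 1] = False
    groups = set()
    for i in range(k):
        j = i
        while j + 1 < k and not different[i, j + 1]:
            j += 1
        groups.add(tuple(order[i : j + 1]))
    # maximal intervals only
    maximal = {
        g
        for g in groups
        if not any(set(g) < set(h) for h in groups if h != g)
    }
    return {frozenset(g) for g in maximal}


def letters_to_partition(result: pd.DataFrame):
    letters = set("".join(result["letters"]))
    idx = {g: i for i, g in enumerate(result["group"])}
    return {
        frozenset(
            idx[g] for g, ls in zip(result["group"], result["letters"]) if ch in ls
        )
        for ch in letters
    }


class TestDuncanMrt:
    def test_extreme_separation_gets_distinct_letters(self, rng):
        vals = np.r_[rng.normal(0, 1, 10), rng.normal(10, 1, 10)]
        grp = ["lo"] * 10 + ["hi"] * 10
        out = duncan_mrt(vals, grp)
        by = dict(zip(out["group"], out["letters"]))
        assert by["hi"] == "a" and by["lo"] == "b"

    def test_single_group_single_letter(self):
        out = duncan_mrt([1.0, 2.0, 3.0], ["g"] * 3)
        assert list(out["letters"]) == ["a"]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(4, 9))
        n = int(rng.integers(4, 9))
        means = rng.uniform(0, 3, k)
        vals, grp = [], []
        for gi in range(k):
            vals.extend(rng.normal(means[gi], 1.0, n))
            grp.extend([f"g{gi}"] * n)
        vals = np.asarray(vals)
        out = duncan_mrt(vals, grp, alpha=0.05)
        df = pd.DataFrame({"value": vals, "group": grp})
        agg = df.groupby("group")["value"].agg(["mean", "count"])
        mse = float(
            df.groupby("group")["value"]
            .apply(lambda v: ((v - v.mean()) ** 2).sum())
            .sum()
        ) / (len(df) - k)
        # oracle works on the aggregated means in the same group order
        expected = brute_force_duncan_partition(
            agg["mean"].to_numpy(), agg["count"].to_numpy(), mse, len(df) - k, 0.05
        )
        got = {
            frozenset(out["group"].iloc[list(g)]) for g in letters_to_partition(out)
        }
        exp = {frozenset(agg.index[list(g)]) for g in expected}
        assert got == exp

    def test_letter_sharing_is_order_consistent(self, rng):
        vals = np.r_[
            rng.normal(0, 1, 8), rng.normal(0.5, 1, 8), rng.normal(1.0, 1, 8)
        ]
        grp = ["a"] * 8 + ["b"] * 8 + ["c"] * 8
        out = duncan_mrt(vals, grp).sort_values("mean", ascending=False)
        letters = list(out["letters"])
        for ch in set("".join(letters)):
            has = [ch in l for l in letters]
            first, last = has.index(True), len(has) - 1 - has[::-1].index(True)
            assert all(has[first : last + 1])

    def test_null_groups_usually_share_a_letter(self):
        """Under H0 all k groups share a letter iff the widest span is
        nonsignificant, which happens with probability (1 - alpha)^(k-1);
        k = 3 keeps that above 90%."""
        hits = 0
        n_sims = 40
        for s in range(n_sims):
            rng = np.random.default_rng(2000 + s)
            vals = rng.normal(0, 1, 3 * 8)
            grp = np.repeat([f"g{i}" for i in range(3)], 8)
            out = duncan_mrt(vals, grp, alpha=0.05)
            if len(set("".join(out["letters"]))) == 1:
                hits += 1
        assert hits >= 0.9 * n_sims
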