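"""Drug analysis: outcome construction, mixed model, Satterthwaite, post-hocs."""

import json
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ddmcompare as dc
from ddmcompare.drug import (COEF_NAMES, RandomInterceptLMM, build_drug_rows,
                             compare_inverse_temperature, fit_drug_model,
                             posthoc_by_task)


def _fit_table(cells):
    """cells: list of (pid, task, condition, session, waic_attr, waic_opt)."""
    rows = []
    for pid, task, cond, sess, wa, wo in cells:
        for model, w in (("attribute", wa), ("option", wo)):
            rows.append({"participant": pid, "task": task, "condition": cond,
                         "session": sess, "model": model, "waic": w,
                         "beta_temperature": np.nan})
    return pd.DataFrame(rows)


class TestBuildRows:
    def test_difference_of_differences_arithmetic(self):
        tab = _fit_table([("p0", "intertemporal", "placebo", 1, 100, 110),
                          ("p0", "intertemporal", "amisulpride", 2, 105, 103)])
        rows = build_drug_rows(tab)
        assert rows.waic_diff_placebo.iloc[0] == -10.0
        assert rows.waic_diff_amisulpride_placebo.iloc[0] == 12.0
        assert rows.amisulpride_session.iloc[0] == 2

    def test_identical_conditions_give_zero(self):
        tab = _fit_table([("p0", "intertemporal", "placebo", 1, 90, 95),
                          ("p0", "intertemporal", "amisulpride", 2, 90, 95)])
        assert build_drug_rows(tab).waic_diff_amisulpride_placebo.iloc[0] == 0.0

    def test_condition_swap_flips_sign(self):
        tab = _fit_table([("p0", "intertemporal", "placebo", 1, 100, 110),
                          ("p0", "intertemporal", "amisulpride", 2, 105, 103)])
        swapped = tab.copy()
        swapped.condition = swapped.condition.map(
            {"placebo": "amisulpride", "amisulpride": "placebo"})
        a = build_drug_rows(tab).waic_diff_amisulpride_placebo.iloc[0]
        b = build_drug_rows(swapped).waic_diff_amisulpride_placebo.iloc[0]
        assert a == -b

    def test_missing_condition_raises(self):
        tab = _fit_table([("p0", "intertemporal", "placebo", 1, 100, 110)])
        with pytest.raises(ValueError, match="missing"):
            build_drug_rows(tab)


def _synthetic_rows(n=40, sb=0.0, slope=-3.0, seed=0, noise=1.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        u = rng.normal(0, np.sqrt(sb))
        wdp = {"intertemporal": rng.normal(0, 2), "interpersonal": rng.normal(0, 2)}
        sess = 1 + (i % 2)
        for task in ("intertemporal", "interpersonal"):
            y = slope * wdp[task] + u + rng.normal(0, noise)
            rows.append({"participant": f"p{i}", "task": task,
                         "amisulpride_session": sess,
                         "waic_diff_placebo": wdp[task],
                         "waic_diff_amisulpride_placebo": y})
    return pd.DataFrame(rows)


class TestRegression:
    def test_recovers_negative_slope(self):
        rows = _synthetic_rows(slope=-3.0, sb=1.0, seed=1)
        rep = fit_drug_model(rows)
        wdp = rep["waic_diff_placebo"]
        # z-scoring rescales the slope by sd(wdp)/sd(y); sign and
        # significance are the meaningful outputs
        assert wdp["estimate"] < 0 and wdp["p"] < 1e-6

    def test_zero_variance_reduces_to_ols(self):
        rows = _synthetic_rows(sb=0.0, seed=2)
        rep = fit_drug_model(rows)
        import statsmodels.api as sm
        from ddmcompare.drug import _design
        X, y = _design(rows)
        ols = sm.OLS(y, X).fit()
        est = rep.coef.set_index("name")["estimate"]
        for j, name in enumerate(COEF_NAMES):
            assert est[name] == pytest.approx(ols.params[j], abs=1e-4)

    def test_affine_recoding_invariance(self):
        rows = _synthetic_rows(sb=0.5, seed=3)
        recoded = rows.copy()
        recoded.amisulpride_session = 10 + 5 * recoded.amisulpride_session
        a = fit_drug_model(rows).coef["estimate"].to_numpy()
        b = fit_drug_model(recoded).coef["estimate"].to_numpy()
        assert np.allclose(a, b, atol=1e-6)

    def test_constant_shift_moves_only_intercept(self):
        rows = _synthetic_rows(sb=0.5, seed=4)
        shifted = rows.copy()
        shifted.waic_diff_amisulpride_placebo += 7.0
        a = fit_drug_model(rows).coef.set_index("name")["estimate"]
        b = fit_drug_model(shifted).coef.set_index("name")["estimate"]
        assert b["intercept"] == pytest.approx(a["intercept"] + 7.0, abs=1e-6)
        for name in COEF_NAMES[1:]:
            assert b[name] == pytest.approx(a[name], abs=1e-6)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not on PATH")
    def test_matches_lmer_satterthwaite(self, tmp_path):
        """Independent oracle: lme4/lmerTest on the identical design."""
        rows = _synthetic_rows(n=30, sb=2.0, slope=-2.0, seed=5)
        from ddmcompare.drug import _design
        X, y = _design(rows)
        df = pd.DataFrame(X, columns=["i", "x1", "x2", "x3", "x12", "x13",
                                      "x23", "x123"])
        df["y"] = y
        df["g"] = rows.participant.to_numpy()
        csv = tmp_path / "rows.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lmerTest)); suppressMessages(library(jsonlite))
            d <- read.csv("{csv}")
            m <- lmer(y ~ x1+x2+x3+x12+x13+x23+x123 + (1|g), data=d, REML=TRUE)
            s <- summary(m)$coefficients
            cat(toJSON(list(est=unname(s[,1]), se=unname(s[,2]),
                            df=unname(s[,3]), p=unname(s[,5])), digits=12))
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout)
        rep = fit_drug_model(rows)
        assert rep.method == "lmm-satterthwaite"
        np.testing.assert_allclose(rep.coef["estimate"], ref["est"], rtol=1e-4)
        np.testing.assert_allclose(rep.coef["se"], ref["se"], rtol=1e-3)
        np.testing.assert_allclose(rep.coef["df"], ref["df"], rtol=0.02)
        np.testing.assert_allclose(rep.coef["p"], ref["p"], rtol=0.05, atol=1e-8)


class TestPosthoc:
    def test_effect_localized_to_one_task(self):
        rng = np.random.default_rng(6)
        rows = _synthetic_rows(n=50, slope=0.0, sb=0.0, seed=6)
        # inject a slope only in the intertemporal task
        it = rows.task == "intertemporal"
        rows.loc[it, "waic_diff_amisulpride_placebo"] += (
            -4.0 * rows.loc[it, "waic_diff_placebo"])
        reps = posthoc_by_task(rows)
        assert reps["intertemporal"]["waic_diff_placebo"]["p"] < 1e-6
        assert reps["interpersonal"]["waic_diff_placebo"]["p"] > 0.05

    def test_permuted_outcome_is_null(self):
        rows = _synthetic_rows(n=50, slope=-3.0, sb=0.0, seed=7)
        rng = np.random.default_rng(8)
        rows.waic_diff_amisulpride_placebo = rng.permutation(
            rows.waic_diff_amisulpride_placebo.to_numpy())
        reps = posthoc_by_task(rows)
        for task in reps:
            assert reps[task]["waic_diff_placebo"]["p"] > 0.01


class TestInverseTemperature:
    def test_matches_hand_computed_paired_t(self):
        ami = [2.0, 2.5, 1.8, 3.0, 2.2]
        pla = [1.5, 2.0, 2.0, 2.4, 1.9]
        rows = []
        for i, (a, p) in enumerate(zip(ami, pla)):
            for cond, bt in (("amisulpride", a), ("placebo", p)):
                rows.append({"participant": f"p{i}", "task": "intertemporal",
                             "condition": cond, "session": 1, "model": "option",
                             "waic": 0.0, "beta_temperature": bt})
        res = compare_inverse_temperature(pd.DataFrame(rows))["intertemporal"]
        d = np.array(ami) - np.array(pla)
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res["t"] == pytest.approx(t_hand, abs=1e-10)
        assert res["n"] == 5

    def test_identical_conditions_give_zero_t(self):
        rows = []
        for i in range(6):
            for cond in ("amisulpride", "placebo"):
                rows.append({"participant": f"p{i}", "task": "interpersonal",
                             "condition": cond, "session": 1, "model": "option",
                             "waic": 0.0, "beta_temperature": 1.0 + i * 0.1})
        res = compare_inverse_temperature(pd.DataFrame(rows))["interpersonal"]
        assert res["t"] == pytest.approx(0.0, abs=1e-12) or np.isnan(res["t"])


class TestLMMInternals:
    def test_gls_equals_ols_when_no_grouping_variance(self):
        rng = np.random.default_rng(9)
        X = np.column_stack([np.ones(60), rng.normal(size=60)])
        y = X @ [1.0, 2.0] + rng.normal(size=60)
        groups = np.repeat(np.arange(30), 2)
        lmm = RandomInterceptLMM(y, X, groups).fit()
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        if lmm.sigma_b2 < 1e-6:
            np.testing.assert_allclose(lmm.beta, beta_ols, atol=1e-5)

    def test_rank_deficiency_rejected(self):
        X = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(ValueError):
            RandomInterceptLMM(np.zeros(20), X, np.arange(20))
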