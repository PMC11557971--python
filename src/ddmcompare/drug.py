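"""Dopamine-antagonist analysis: does the drug attenuate the dominant strategy?

The outcome per participant x task is a difference of differences of model
fits:

    waic_diff_placebo            = (WAIC_attribute - WAIC_option) under placebo
    waic_diff_amisulpride_placebo = (WAIC_attribute - WAIC_option)_amisulpride
                                    - (WAIC_attribute - WAIC_option)_placebo

The outcome is regressed on Task (0 = interpersonal, 1 = intertemporal),
Session (which session carried the antagonist), the dominant-strategy
measure ``waic_diff_placebo``, and all interactions, in a linear mixed model
with a participant random intercept. All predictors are z-transformed before
entry so that main effects are interpretable without a reference category.
Degrees of freedom use the Satterthwaite approximation from the REML
covariance of the variance components; when the random-intercept variance
collapses to zero the model reduces to ordinary least squares and residual
degrees of freedom are reported instead.

A negative ``waic_diff_placebo`` coefficient means the antagonist shifts
model fit *away* from whichever strategy dominated under placebo.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import ATTRIBUTE, OPTION, simulate_drug_cohort
from .inference import fit_ddm
from .task_design import INTERPERSONAL, INTERTEMPORAL

__all__ = [
    "RegressionReport",
    "build_drug_rows",
    "fit_drug_model",
    "posthoc_by_task",
    "compare_inverse_temperature",
    "fit_conditions",
    "run_drug_pipeline",
    "RandomInterceptLMM",
]

COEF_NAMES = ("intercept", "task", "session", "waic_diff_placebo",
              "task:session", "task:waic_diff_placebo",
              "session:waic_diff_placebo", "task:session:waic_diff_placebo")


@dataclass
class RegressionReport:
    coef: pd.DataFrame                # name, estimate, se, t, df, p
    method: str                       # "lmm-satterthwaite" or "ols"
    sigma_b2: float                   # random-intercept variance
    sigma_e2: float                   # residual variance

    def __getitem__(self, name: str) -> dict:
        row = self.coef.set_index("name").loc[name]
        return row.to_dict()


class RandomInterceptLMM:
    """Linear mixed model with one random intercept per group, fitted by REML.

    The grouped structure makes V block diagonal, so the profiled REML
    objective, the GLS fixed effects, and the Satterthwaite degrees of
    freedom are all computed with closed-form block inverses.
    """

    def __init__(self, y, X, groups):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        codes, _ = pd.factorize(np.asarray(groups))
        self.group_idx = [np.flatnonzero(codes == g) for g in range(codes.max() + 1)]
        self.n, self.p = self.X.shape
        if np.linalg.matrix_rank(self.X) < self.p:
            raise ValueError("design matrix is rank deficient")

    def _gls_pieces(self, sb2: float, se2: float):
        XtVX = np.zeros((self.p, self.p))
        XtVy = np.zeros(self.p)
        ytVy = 0.0
        logdet = 0.0
        for idx in self.group_idx:
            Xg = self.X[idx]
            yg = self.y[idx]
            ng = idx.size
            c = sb2 / (se2 * (se2 + ng * sb2))
            XtVX += Xg.T @ Xg / se2 - c * np.outer(Xg.sum(0), Xg.sum(0))
            XtVy += Xg.T @ yg / se2 - c * Xg.sum(0) * yg.sum()
            ytVy += yg @ yg / se2 - c * yg.sum() ** 2
            logdet += (ng - 1) * np.log(se2) + np.log(se2 + ng * sb2)
        return XtVX, XtVy, ytVy, logdet

    def reml_nll(self, theta) -> float:
        sb2, se2 = theta
        if se2 <= 0 or sb2 < 0:
            return np.inf
        XtVX, XtVy, ytVy, logdet = self._gls_pieces(sb2, se2)
        sign, logdet_xvx = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtVX, XtVy)
        rss = ytVy - beta @ XtVy
        return 0.5 * (logdet + logdet_xvx + rss)

    def fit(self):
        var0 = self.y.var(ddof=1) if self.n > 1 else 1.0
        best = None
        for f in (0.5, 0.1, 0.9):
            res = optimize.minimize(
                lambda lt: self.reml_nll(np.exp(lt)),
                x0=np.log([max(f * var0, 1e-8), max((1 - f) * var0, 1e-8)]),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
            if best is None or res.fun < best.fun:
                best = res
        self.sigma_b2, self.sigma_e2 = np.exp(best.x)
        XtVX, XtVy, _, _ = self._gls_pieces(self.sigma_b2, self.sigma_e2)
        self.cov_beta = np.linalg.inv(XtVX)
        self.beta = self.cov_beta @ XtVy
        return self

    def satterthwaite_df(self, j: int) -> float:
        """Satterthwaite df for coefficient j: 2 f^2 / (g' A g) with
        f = Var(beta_j), g its gradient in the variance components, and A
        the inverse REML information of (sigma_b2, sigma_e2)."""
        theta = np.array([self.sigma_b2, self.sigma_e2])

        def f_of(th):
            XtVX, _, _, _ = self._gls_pieces(th[0], th[1])
            return np.linalg.inv(XtVX)[j, j]

        h = np.maximum(1e-6 * np.abs(theta), 1e-10)
        grad = np.empty(2)
        for i in range(2):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h[i]
            tm[i] = max(tm[i] - h[i], 0.0 if i == 0 else 1e-12)
            grad[i] = (f_of(tp) - f_of(tm)) / (tp[i] - tm[i])
        # numerical Hessian of the REML objective
        H = np.empty((2, 2))
        hh = np.maximum(1e-4 * np.abs(theta), 1e-8)
        for i in range(2):
            for k in range(2):
                tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
                tpp[i] += hh[i]; tpp[k] += hh[k]
                tpm[i] += hh[i]; tpm[k] -= hh[k]
                tmp[i] -= hh[i]; tmp[k] += hh[k]
                tmm[i] -= hh[i]; tmm[k] -= hh[k]
                H[i, k] = ((self.reml_nll(tpp) - self.reml_nll(tpm)
                            - self.reml_nll(tmp) + self.reml_nll(tmm))
                           / (4 * hh[i] * hh[k]))
        try:
            A = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return float(self.n - self.p)
        denom = grad @ A @ grad
        fj = self.cov_beta[j, j]
        if denom <= 0:
            return float(self.n - self.p)
        return float(2.0 * fj**2 / denom)


def build_drug_rows(fit_table: pd.DataFrame) -> pd.DataFrame:
    """Assemble the per-participant x task difference-of-differences outcomes.

    ``fit_table`` is tidy with columns participant, task, condition
    ('amisulpride'/'placebo'), session, model, waic. Raises if any of the
    four fits for a participant x task cell is missing.
    """
    required = {"participant", "task", "condition", "session", "model", "waic"}
    missing = required - set(fit_table.columns)
    if missing:
        raise ValueError(f"fit_table lacks columns {sorted(missing)}")
    rows = []
    for (pid, task), grp in fit_table.groupby(["participant", "task"], sort=True):
        wd = {}
        for cond in ("placebo", "amisulpride"):
            sub = grp[grp.condition == cond]
            waics = {m: sub[sub.model == m]["waic"] for m in (ATTRIBUTE, OPTION)}
            if any(v.empty for v in waics.values()):
                raise ValueError(f"missing {cond} fits for {pid}/{task}")
            wd[cond] = float(waics[ATTRIBUTE].iloc[0] - waics[OPTION].iloc[0])
        ami_session = int(grp[grp.condition == "amisulpride"]["session"].iloc[0])
        rows.append({"participant": pid, "task": task,
                     "amisulpride_session": ami_session,
                     "waic_diff_placebo": wd["placebo"],
                     "waic_diff_amisulpride_placebo": wd["amisulpride"] - wd["placebo"]})
    return pd.DataFrame(rows)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant predictor")
    return (x - x.mean()) / sd


def _design(rows: pd.DataFrame):
    task = _zscore((rows.task == INTERTEMPORAL).to_numpy(float))
    session = _zscore(rows.amisulpride_session.to_numpy(float))
    wdp = _zscore(rows.waic_diff_placebo.to_numpy(float))
    X = np.column_stack([np.ones(len(rows)), task, session, wdp,
                         task * session, task * wdp, session * wdp,
                         task * session * wdp])
    return X, rows.waic_diff_amisulpride_placebo.to_numpy(float)


def fit_drug_model(rows: pd.DataFrame) -> RegressionReport:
    """The full-factorial mixed regression of the drug-shift outcome.

    A negative ``waic_diff_placebo`` estimate indicates attenuation of the
    dominant value-comparison strategy under the antagonist.
    """
    if rows.participant.nunique() < 10:
        raise ValueError("need at least 10 participants")
    X, y = _design(rows)
    lmm = RandomInterceptLMM(y, X, rows.participant.to_numpy()).fit()
    if lmm.sigma_b2 < 1e-8 * max(lmm.sigma_e2, 1e-12):
        return _ols_report(X, y, rows, note="ols")
    records = []
    for j, name in enumerate(COEF_NAMES):
        se = float(np.sqrt(lmm.cov_beta[j, j]))
        t = float(lmm.beta[j] / se)
        df = lmm.satterthwaite_df(j)
        records.append({"name": name, "estimate": float(lmm.beta[j]), "se": se,
                        "t": t, "df": df, "p": float(2 * stats.t.sf(abs(t), df))})
    return RegressionReport(pd.DataFrame(records), "lmm-satterthwaite",
                            float(lmm.sigma_b2), float(lmm.sigma_e2))


def _ols_report(X, y, rows, note="ols", names=COEF_NAMES) -> RegressionReport:
    import statsmodels.api as sm
    res = sm.OLS(y, X).fit()
    df = float(res.df_resid)
    records = [{"name": name, "estimate": float(res.params[j]),
                "se": float(res.bse[j]), "t": float(res.tvalues[j]), "df": df,
                "p": float(res.pvalues[j])}
               for j, name in enumerate(names)]
    return RegressionReport(pd.DataFrame(records), note, 0.0,
                            float(res.scale))


def posthoc_by_task(rows: pd.DataFrame) -> dict:
    """Within-task OLS of the outcome on z-scored Session and waic_diff_placebo."""
    out = {}
    for task, grp in rows.groupby("task"):
        session = _zscore(grp.amisulpride_session.to_numpy(float))
        wdp = _zscore(grp.waic_diff_placebo.to_numpy(float))
        X = np.column_stack([np.ones(len(grp)), session, wdp])
        y = grp.waic_diff_amisulpride_placebo.to_numpy(float)
        out[task] = _ols_report(X, y, grp,
                                names=("intercept", "session", "waic_diff_placebo"))
    return out


def compare_inverse_temperature(fit_table: pd.DataFrame) -> dict:
    """Paired t-test on posterior-mean inverse temperatures, drug vs placebo.

    A positive t means choice consistency *increased* under the antagonist --
    the control that rules out a pure decision-noise account of the main
    effect. Requires a ``beta_temperature`` column for option-model rows.
    """
    out = {}
    opt = fit_table[fit_table.model == OPTION]
    for task, grp in opt.groupby("task"):
        wide = grp.pivot(index="participant", columns="condition",
                         values="beta_temperature").dropna()
        if wide.empty:
            raise ValueError(f"no paired inverse-temperature data for {task}")
        t, p = stats.ttest_rel(wide["amisulpride"], wide["placebo"])
        out[task] = {"t": float(t), "p": float(p), "n": int(len(wide)),
                     "mean_amisulpride": float(wide["amisulpride"].mean()),
                     "mean_placebo": float(wide["placebo"].mean())}
    return out


def fit_conditions(records, specs, seed: int = 0, **fit_kwargs) -> pd.DataFrame:
    """Fit both models to every participant x task x condition cell.

    Returns the tidy fit table consumed by :func:`build_drug_rows` and
    :func:`compare_inverse_temperature`.
    """
    frame = pd.DataFrame({
        "participant": [r.participant for r in records],
        "task": [r.trial.task for r in records],
        "condition": [r.condition for r in records],
        "session": [r.session for r in records],
        "i": np.arange(len(records)),
    })
    rng = np.random.default_rng(seed)
    rows = []
    for (pid, task, cond), grp in frame.groupby(["participant", "task", "condition"],
                                                sort=True):
        cell = [records[i] for i in grp["i"]]
        session = int(grp["session"].iloc[0])
        for model in (ATTRIBUTE, OPTION):
            fit = fit_ddm(cell, model, seed=int(rng.integers(0, 2**31 - 1)),
                          **fit_kwargs)
            rows.append({
                "participant": pid, "task": task, "condition": cond,
                "session": session, "model": model, "waic": fit.waic,
                "converged": fit.converged,
                "beta_temperature": (fit.posterior_mean()["beta_temperature"]
                                     if model == OPTION else np.nan)})
    return pd.DataFrame(rows)


def run_drug_pipeline(n: int = 56, effect_size: float = 0.5, seed: int = 0,
                      contaminant_rate: float = 0.06,
                      n_trials: tuple[int, int] = (20, 54),
                      **fit_kwargs) -> dict:
    """End to end: simulate the crossover study, fit every cell, regress.

    Returns a dict with the simulated ``specs``, the tidy ``fit_table``, the
    outcome ``rows``, the mixed-model ``report``, per-task ``posthoc``
    reports, and the inverse-``temperature`` control test.
    """
    rng = np.random.default_rng(seed)
    records, specs = simulate_drug_cohort(n, effect_size, rng,
                                          contaminant_rate=contaminant_rate,
                                          n_trials=n_trials)
    fit_table = fit_conditions(records, specs,
                               seed=int(rng.integers(0, 2**31 - 1)), **fit_kwargs)
    rows = build_drug_rows(fit_table)
    report = fit_drug_model(rows)
    return {"specs": specs, "fit_table": fit_table, "rows": rows,
            "report": report, "posthoc": posthoc_by_task(rows),
            "temperature": compare_inverse_temperature(fit_table)}
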