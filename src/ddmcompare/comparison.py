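"""Group-level comparison of the attribute-wise and option-wise models.

Per-participant WAICs are the unit of analysis throughout: the group test is
a Wilcoxon signed-rank on the per-participant WAIC differences (group sums
and means are reported for description only, since aggregation conventions
differ across software). Prediction accuracy is computed in-sample and by
repeated 90/10 cross-validation; model identifiability by refitting both
candidates to data simulated from known parameters; adequacy by posterior
predictive checks on the signed (choice-coded) RT distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ATTRIBUTE, OPTION, simulate_behavior
from .ddm import drift_rates, upper_choice_probability
from .inference import FitResult, exclude_fast_trials, fit_ddm
from ._kernels import simulate_walks

__all__ = [
    "ComparisonResult",
    "RecoveryResult",
    "wilcoxon_signed_rank",
    "kendall_tau",
    "predict_choices",
    "disagreement_rate",
    "cross_validate",
    "model_recovery",
    "posterior_predictive",
    "sanity_correlations",
    "compare_models",
]

#: fixed signed-RT binning for posterior predictive overlap (seconds); 0.5 s
#: bins keep expected counts per bin large enough that the overlap estimator
#: is not badly downward-biased at ~90 observed trials
PPC_BINS = np.arange(-5.5, 5.51, 0.5)


@dataclass
class ComparisonResult:
    table: pd.DataFrame               # per-participant WAICs, accuracies, disagreement
    wilcoxon_w: float
    wilcoxon_p: float
    accuracy: dict                    # model -> mean in-sample accuracy
    disagreement: float               # mean fraction of trials with differing predictions

    @property
    def waic_diffs(self) -> np.ndarray:
        return self.table["waic_diff"].to_numpy()


@dataclass
class RecoveryResult:
    generating_model: str
    task: str
    wins: dict                        # candidate model -> datasets it best fits
    waic_diffs: np.ndarray            # attribute - option per dataset
    wilcoxon_w: float
    wilcoxon_p: float

    @property
    def n_datasets(self) -> int:
        return int(sum(self.wins.values()))

    @property
    def recovery_rate(self) -> float:
        return self.wins[self.generating_model] / self.n_datasets


def wilcoxon_signed_rank(diffs):
    """Two-sided Wilcoxon signed-rank test.

    ``W`` is the sum of the ranks of the positive differences after dropping
    zeros, with average ranks for ties. The p-value is exact (sign-flip
    distribution) for n <= 25 without ties, otherwise a normal approximation
    with continuity and tie corrections.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n
    if n <= 25 and not has_ties:
        p = _exact_signed_rank_p(n, w_pos)
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if var <= 0:
            raise ValueError("zero variance in signed-rank statistic")
        z = (w_pos - mean - 0.5 * np.sign(w_pos - mean)) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    return w_pos, min(p, 1.0)


def _exact_signed_rank_p(n: int, w: float):
    """Exact two-sided p by dynamic programming over the 2^n sign flips."""
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    total = counts.sum()
    w = int(round(w))
    p_le = counts[: w + 1].sum() / total
    p_ge = counts[w:].sum() / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def kendall_tau(x, y):
    """Kendall's tau-b (tie-corrected) with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("kendall_tau requires variation in both inputs")
    res = stats.kendalltau(x, y)
    return float(res.statistic), float(res.pvalue)


def _p_distant(fit: FitResult, trials, posterior_average: bool = False,
               max_draws: int = 200) -> np.ndarray:
    params = fit.point_params()
    if not posterior_average:
        nu = drift_rates(trials, params)
        if fit.choice_only:
            return 1.0 / (1.0 + np.exp(-nu))
        return np.array([upper_choice_probability((v, params.alpha, params.zeta))
                         for v in nu])
    flat = fit.draws.reshape(-1, 6)
    idx = np.linspace(0, flat.shape[0] - 1, min(max_draws, flat.shape[0])).astype(int)
    ps = np.zeros(len(trials))
    for row in flat[idx]:
        p = _params_from_row(fit, row)
        nu = drift_rates(trials, p)
        if fit.choice_only:
            ps += 1.0 / (1.0 + np.exp(-nu))
        else:
            ps += np.array([upper_choice_probability((v, p.alpha, p.zeta)) for v in nu])
    return ps / idx.size


def _params_from_row(fit: FitResult, row):
    from .ddm import AttributeParams, OptionParams
    if fit.model == ATTRIBUTE:
        return AttributeParams(row[0], row[1], row[2], max(row[3], 1e-3),
                               min(max(row[4], 1e-3), 1 - 1e-3), max(row[5], 0.0),
                               include_intercept=fit.include_intercept)
    return OptionParams(max(row[0], 0.0), row[1], max(row[2], 1e-6),
                        max(row[3], 1e-3), min(max(row[4], 1e-3), 1 - 1e-3),
                        max(row[5], 0.0),
                        include_sigmoid=fit.include_sigmoid and not fit.choice_only)


def predict_choices(fit: FitResult, records=None, posterior_average: bool = False):
    """Trial-wise P(distant) and prediction accuracy.

    Predictions use the absorption probability at the posterior-mean
    parameters (or the posterior-averaged predictive probability when
    ``posterior_average`` is set). A predicted probability of exactly 0.5 is
    scored as half a hit.
    """
    records = fit.records if records is None else records
    records = [r for r in records if not r.omitted]
    trials = [r.trial for r in records]
    p = _p_distant(fit, trials, posterior_average)
    observed = np.array([r.boundary == "upper" for r in records])
    hits = np.where(p == 0.5, 0.5, (p > 0.5) == observed)
    return p, float(np.mean(hits))


def disagreement_rate(fit_a: FitResult, fit_b: FitResult, records=None) -> float:
    """Fraction of trials on which the two fitted models predict different choices."""
    records = fit_a.records if records is None else records
    records = [r for r in records if not r.omitted]
    trials = [r.trial for r in records]
    pa = _p_distant(fit_a, trials) > 0.5
    pb = _p_distant(fit_b, trials) > 0.5
    return float(np.mean(pa != pb))


def cross_validate(records, model: str, repeats: int = 10, test_frac: float = 0.1,
                   rng=None, **fit_kwargs):
    """Repeated random 90/10 split cross-validation for one participant.

    Fits on the training fraction and scores held-out choices with
    :func:`predict_choices`; returns ``(mean_accuracy, per_repeat_accuracies)``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    kept, _ = exclude_fast_trials(records)
    n = len(kept)
    n_test = max(1, int(round(test_frac * n)))
    if n - n_test < 10:
        raise ValueError("too few trials for cross-validation")
    accs = []
    for rep in range(repeats):
        idx = rng.permutation(n)
        test_idx = set(idx[:n_test].tolist())
        train = [kept[i] for i in range(n) if i not in test_idx]
        test = [kept[i] for i in range(n) if i in test_idx]
        fit = fit_ddm(train, model, seed=int(rng.integers(0, 2**31 - 1)),
                      **fit_kwargs)
        _, acc = predict_choices(fit, test)
        accs.append(acc)
    return float(np.mean(accs)), np.array(accs)


def compare_models(records_by_participant: dict, seed: int = 0,
                   **fit_kwargs) -> ComparisonResult:
    """Fit both models to every participant and run the group comparison."""
    rows = []
    rng = np.random.default_rng(seed)
    for pid, records in records_by_participant.items():
        s1, s2 = (int(rng.integers(0, 2**31 - 1)) for _ in range(2))
        fit_a = fit_ddm(records, ATTRIBUTE, seed=s1, **fit_kwargs)
        fit_o = fit_ddm(records, OPTION, seed=s2, **fit_kwargs)
        _, acc_a = predict_choices(fit_a)
        _, acc_o = predict_choices(fit_o)
        rows.append({"participant": pid,
                     "waic_attribute": fit_a.waic, "waic_option": fit_o.waic,
                     "waic_diff": fit_a.waic - fit_o.waic,
                     "acc_attribute": acc_a, "acc_option": acc_o,
                     "disagreement": disagreement_rate(fit_a, fit_o)})
    table = pd.DataFrame(rows)
    w, p = wilcoxon_signed_rank(table["waic_diff"].to_numpy())
    return ComparisonResult(
        table=table, wilcoxon_w=w, wilcoxon_p=p,
        accuracy={ATTRIBUTE: float(table["acc_attribute"].mean()),
                  OPTION: float(table["acc_option"].mean())},
        disagreement=float(table["disagreement"].mean()))


def model_recovery(specs, task: str, generating_model: str, trials_fn,
                   rng=None, contaminant_rate: float = 0.0,
                   **fit_kwargs) -> RecoveryResult:
    """Refit both candidates to data simulated from known parameters.

    ``trials_fn(rng) -> list[Trial]`` supplies a fresh trial set per
    simulated dataset. A dataset counts as recovered when the generating
    model attains the strictly lower WAIC (ties count as errors).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    wins = {ATTRIBUTE: 0, OPTION: 0}
    diffs = []
    for spec in specs:
        trials = trials_fn(rng)
        records = simulate_behavior(spec, trials, contaminant_rate, rng,
                                    model=generating_model)
        s1, s2 = (int(rng.integers(0, 2**31 - 1)) for _ in range(2))
        fit_a = fit_ddm(records, ATTRIBUTE, seed=s1, **fit_kwargs)
        fit_o = fit_ddm(records, OPTION, seed=s2, **fit_kwargs)
        diff = fit_a.waic - fit_o.waic
        diffs.append(diff)
        if diff < 0:
            wins[ATTRIBUTE] += 1
        elif diff > 0:
            wins[OPTION] += 1
        else:  # exact tie: an error for whichever model generated the data
            wins[OPTION if generating_model == ATTRIBUTE else ATTRIBUTE] += 1
    diffs = np.array(diffs)
    w, p = wilcoxon_signed_rank(diffs)
    return RecoveryResult(generating_model=generating_model, task=task,
                          wins=wins, waic_diffs=diffs, wilcoxon_w=w, wilcoxon_p=p)


def posterior_predictive(fit: FitResult, n_sims: int = 1000, rng=None,
                         bins: np.ndarray = PPC_BINS, dt: float = 0.001):
    """Simulate signed RTs from the posterior and compare with the observed.

    Signed RT codes the choice: negative for the closer option, positive for
    the more distant one. One posterior draw is used per simulated trial.
    Returns ``(simulated_signed_rts, observed_signed_rts, overlap)`` where
    overlap is ``1 - 0.5 * sum |p_sim - p_obs|`` over the fixed binning.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    records = [r for r in fit.records if not r.omitted]
    trials = [r.trial for r in records]
    flat = fit.draws.reshape(-1, 6)
    draw_idx = rng.integers(0, flat.shape[0], n_sims)
    trial_idx = rng.integers(0, len(trials), n_sims)
    nu = np.empty(n_sims)
    alpha = np.empty(n_sims)
    zeta = np.empty(n_sims)
    tau = np.empty(n_sims)
    for s in range(n_sims):
        p = _params_from_row(fit, flat[draw_idx[s]])
        nu[s] = drift_rates([trials[trial_idx[s]]], p)[0]
        alpha[s], zeta[s], tau[s] = p.alpha, p.zeta, p.tau
    seed = int(rng.integers(0, 2**31 - 1))
    boundary, rt = simulate_walks(nu, alpha, zeta, tau, dt, 8.0, seed)
    ok = (boundary >= 0) & (rt <= 5.0)
    signed_sim = np.where(boundary[ok] == 1, rt[ok], -rt[ok])
    signed_obs = np.array([r.rt if r.boundary == "upper" else -r.rt for r in records])
    h_sim, _ = np.histogram(signed_sim, bins=bins)
    h_obs, _ = np.histogram(signed_obs, bins=bins)
    if h_sim.sum() == 0 or h_obs.sum() == 0:
        overlap = 0.0
    else:
        p_sim = h_sim / h_sim.sum()
        p_obs = h_obs / h_obs.sum()
        overlap = float(1.0 - 0.5 * np.abs(p_sim - p_obs).sum())
    return signed_sim, signed_obs, overlap


def sanity_correlations(attribute_fits, option_fits, records_by_participant: dict):
    """Kendall tau-b checks that the fitted parameters track raw behavior.

    The summed attribute drift weights (intercept + reward + distance) should
    correlate positively, and the log discount rate negatively, with each
    participant's proportion of distant choices.
    """
    if len(attribute_fits) < 10:
        raise ValueError("need at least 10 participants for rank correlations")
    prop = []
    for fit in attribute_fits:
        recs = [r for r in records_by_participant[fit.participant] if not r.omitted]
        prop.append(np.mean([r.boundary == "upper" for r in recs]))
    prop = np.array(prop)
    drift_sum = np.array([sum(f.posterior_mean()[k] for k in
                              ("beta_intercept", "beta_reward", "beta_distance"))
                          for f in attribute_fits])
    log_k = np.array([f.posterior_mean()["log_k"] for f in option_fits])
    tau_drift, p_drift = kendall_tau(drift_sum, prop)
    tau_k, p_k = kendall_tau(log_k, prop)
    return {"drift_sum": {"tau": tau_drift, "p": p_drift},
            "log_k": {"tau": tau_k, "p": p_k}}
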