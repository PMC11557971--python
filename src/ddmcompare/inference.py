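"""Per-participant Bayesian estimation of the choice models.

Each participant x task x model combination is fitted separately (no
hierarchy) by adaptive Metropolis-within-Gibbs under flat uniform priors:
drift-related weights on [-10, 10], positivity-constrained parameters on
documented positive ranges, and the non-decision time bounded above by the
smallest retained RT. Convergence is assessed with the split Gelman-Rubin
statistic; model fit with the widely applicable information criterion
computed from the pointwise posterior log likelihoods.

Trials with implausibly fast responses (< 250 ms by default) and response
omissions are excluded from the likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from . import _kernels
from .cohort import ATTRIBUTE, OPTION, ChoiceRecord
from .ddm import AttributeParams, OptionParams

__all__ = [
    "PriorSpec",
    "FitResult",
    "NonConvergenceWarning",
    "exclude_fast_trials",
    "default_priors",
    "fit_ddm",
    "fit_choice_only",
    "compute_waic",
    "split_rhat",
    "FAST_RT_THRESHOLD_S",
]

FAST_RT_THRESHOLD_S = 0.250

PARAM_NAMES = {
    ATTRIBUTE: ("beta_intercept", "beta_reward", "beta_distance", "alpha", "zeta", "tau"),
    OPTION: ("beta_temperature", "log_k", "v_lim", "alpha", "zeta", "tau"),
}


class NonConvergenceWarning(UserWarning):
    """Raised (as a warning) when R-hat stays above threshold after restarts."""


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior box: parameter name -> (lower, upper)."""

    bounds: dict

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"empty prior interval for {name}: ({lo}, {hi})")

    def arrays(self, names) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([self.bounds[n][0] for n in names])
        ub = np.array([self.bounds[n][1] for n in names])
        return lb, ub


def default_priors(model: str, min_rt: float) -> PriorSpec:
    """The default uniform prior box for one model family.

    Drift weights span [-10, 10]; the remaining parameters are restricted to
    positive ranges, with the non-decision time capped just below the
    smallest retained RT (the likelihood is zero beyond it).
    """
    common = {"alpha": (0.05, 5.0), "zeta": (0.05, 0.95),
              "tau": (0.01, max(min_rt - 0.01, 0.02))}
    if model == ATTRIBUTE:
        drift = {"beta_intercept": (-10.0, 10.0), "beta_reward": (-10.0, 10.0),
                 "beta_distance": (-10.0, 10.0)}
    else:
        drift = {"beta_temperature": (0.0, 10.0), "log_k": (-10.0, 3.0),
                 "v_lim": (0.01, 10.0)}
    return PriorSpec({**drift, **common})


@dataclass
class FitResult:
    """Posterior summary for one participant x task x model fit."""

    model: str
    participant: str
    task: str
    param_names: tuple
    sampled: tuple                      # names actually sampled (variant-dependent)
    draws: np.ndarray                   # (chains, keep, 6)
    loglik: np.ndarray                  # (trials, chains*keep)
    rhat: dict
    waic: float
    lppd: float
    p_waic: float
    n_trials_used: int
    n_trials_excluded: int
    include_intercept: bool = True
    include_sigmoid: bool = True
    choice_only: bool = False
    converged: bool = True
    accept_rate: dict = field(default_factory=dict)
    seed: int = 0
    records: list = field(default_factory=list, repr=False)

    def posterior_mean(self) -> dict:
        flat = self.draws.reshape(-1, self.draws.shape[-1])
        return {n: float(flat[:, i].mean()) for i, n in enumerate(self.param_names)}

    def point_params(self):
        """Posterior-mean parameters as a model parameter object.

        For choice-only fits the diffusion parameters are placeholders (they
        are not part of the model); only the drift weights are meaningful.
        """
        m = self.posterior_mean()
        if self.choice_only:
            m.setdefault("alpha", 1.0)
            m["alpha"] = m["alpha"] if m["alpha"] > 0 else 1.0
            m["zeta"], m["tau"] = 0.5, 0.0
        if self.model == ATTRIBUTE:
            return AttributeParams(m["beta_intercept"], m["beta_reward"],
                                   m["beta_distance"], m["alpha"], m["zeta"],
                                   m["tau"], include_intercept=self.include_intercept)
        return OptionParams(m["beta_temperature"], m["log_k"], max(m["v_lim"], 1e-6),
                            m["alpha"], m["zeta"], m["tau"],
                            include_sigmoid=self.include_sigmoid and not self.choice_only)


def exclude_fast_trials(records, threshold: float = FAST_RT_THRESHOLD_S):
    """Drop implausibly fast trials (rt < threshold, strict) and omissions.

    Returns ``(kept_records, excluded_fast_fraction)`` where the fraction is
    relative to all non-omitted records.
    """
    if not records:
        raise ValueError("records must be nonempty")
    responded = [r for r in records if not r.omitted]
    kept = [r for r in responded if r.rt >= threshold]
    if not kept:
        raise ValueError("no records remain after fast-trial exclusion")
    frac = 1.0 - len(kept) / len(responded) if responded else 0.0
    return kept, frac


def records_to_arrays(records):
    """Flatten non-omitted records into the contiguous arrays the kernels use."""
    trials = [r.trial for r in records]
    rdiff = np.array([t.reward_diff for t in trials])
    ddiff = np.array([t.distance_diff for t in trials])
    m_close = np.array([t.option_close.magnitude for t in trials])
    d_close = np.array([t.option_close.distance for t in trials])
    m_distant = np.array([t.option_distant.magnitude for t in trials])
    d_distant = np.array([t.option_distant.distance for t in trials])
    upper = np.array([1 if r.boundary == "upper" else 0 for r in records], dtype=np.int8)
    rt = np.array([r.rt for r in records])
    return rdiff, ddiff, m_close, d_close, m_distant, d_distant, upper, rt


def compute_waic(loglik: np.ndarray):
    """WAIC from a pointwise log-likelihood matrix (trials x draws).

    ``lppd = sum_i log mean_s exp(ll_is)`` (log-sum-exp stabilized);
    ``p_waic = sum_i var_s(ll_is)`` with the n-1 (sample) variance;
    ``waic = -2 (lppd - p_waic)``.
    """
    loglik = np.asarray(loglik, dtype=float)
    if loglik.ndim != 2 or loglik.shape[1] < 2:
        raise ValueError("loglik must be (trials x draws) with >= 2 draws")
    if not np.all(np.isfinite(loglik)):
        raise ValueError("non-finite pointwise log likelihoods")
    n_draws = loglik.shape[1]
    lppd = float(np.sum(logsumexp(loglik, axis=1) - np.log(n_draws)))
    row_var = np.var(loglik, axis=1, ddof=1)
    # a degenerate (constant) row has exactly zero penalty; guard against
    # the ulp-level residue of pairwise summation
    row_var[loglik.max(axis=1) == loglik.min(axis=1)] = 0.0
    p_waic = float(np.sum(row_var))
    waic = -2.0 * (lppd - p_waic)
    return lppd, p_waic, waic


def split_rhat(chain_draws: np.ndarray) -> float:
    """Split Gelman-Rubin statistic for one parameter, draws (chains, n)."""
    m, n = chain_draws.shape
    half = n // 2
    if half < 2:
        return np.nan
    splits = chain_draws[:, :2 * half].reshape(m * 2, half)
    means = splits.mean(axis=1)
    variances = splits.var(axis=1, ddof=1)
    W = variances.mean()
    B = half * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_hat = (half - 1) / half * W + B / half
    return float(np.sqrt(var_hat / W))


def _run_sampler(records, model, include_intercept, include_sigmoid, choice_only,
                 prior, chains, samples, burn, seed):
    arrays = records_to_arrays(records)
    names = PARAM_NAMES[model]
    lb, ub = prior.arrays(names)
    mask = np.ones(6, dtype=bool)
    fixed = np.zeros(6)
    if model == ATTRIBUTE and not include_intercept:
        mask[0] = False
    if model == OPTION and (not include_sigmoid or choice_only):
        mask[2] = False                       # v_lim unused without the sigmoid
        fixed[2] = 1.0
    if choice_only:
        mask[3:] = False                      # no diffusion parameters
        fixed[3], fixed[4], fixed[5] = 1.0, 0.5, 0.0
    model_id = _kernels.MODEL_ATTRIBUTE if model == ATTRIBUTE else _kernels.MODEL_OPTION
    n_keep = samples - burn
    if n_keep < 2:
        raise ValueError("samples must exceed burn by at least 2")
    draws, ll, acc = _kernels.mh_gibbs_sample(
        model_id, include_intercept, include_sigmoid, choice_only,
        *arrays, lb, ub, mask, fixed, chains, n_keep, burn, seed,
        _kernels.SERIES_EPS)
    return draws, ll, acc, mask, names


def fit_ddm(records, model: str, include_intercept: bool = True,
            include_sigmoid: bool = True, prior: PriorSpec | None = None,
            chains: int = 2, samples: int = 10_000, burn: int = 5_000,
            seed: int = 0, exclusion_threshold: float = FAST_RT_THRESHOLD_S,
            max_restarts: int = 2, rhat_threshold: float = 1.05,
            choice_only: bool = False, participant: str | None = None) -> FitResult:
    """Fit one diffusion (or choice-only) model to one participant's records.

    Fast trials and omissions are excluded before fitting. Two independent
    chains (by default) are run; if any split R-hat exceeds
    ``rhat_threshold`` the fit is restarted with a fresh seed up to
    ``max_restarts`` times, after which the result is flagged
    (``converged=False``) with a :class:`NonConvergenceWarning`.
    """
    if model not in (ATTRIBUTE, OPTION):
        raise ValueError(f"model must be '{ATTRIBUTE}' or '{OPTION}'")
    n_all = len(records)
    kept, _ = exclude_fast_trials(records, exclusion_threshold)
    if len(kept) < 10:
        raise ValueError(f"only {len(kept)} usable trials after exclusion")
    if prior is None:
        prior = default_priors(model, min(r.rt for r in kept))

    names = PARAM_NAMES[model]
    last = None
    for restart in range(max_restarts + 1):
        run_seed = (seed + 7919 * restart) % (2**31 - 1)
        draws, ll, acc, mask, names = _run_sampler(
            kept, model, include_intercept, include_sigmoid, choice_only,
            prior, chains, samples, burn, run_seed)
        rhat = {n: (split_rhat(draws[:, :, i]) if mask[i] else 1.0)
                for i, n in enumerate(names)}
        converged = all(not np.isfinite(v) or v < rhat_threshold for v in rhat.values())
        last = (draws, ll, acc, mask, rhat, converged, run_seed)
        if converged:
            break
    draws, ll, acc, mask, rhat, converged, run_seed = last
    if not converged:
        warnings.warn(
            f"fit did not converge (max R-hat "
            f"{max(v for v in rhat.values() if np.isfinite(v)):.3f}) for "
            f"{model}/{participant}", NonConvergenceWarning)
    lppd, p_waic, waic = compute_waic(ll)
    task = kept[0].trial.task
    return FitResult(
        model=model, participant=participant or kept[0].participant, task=task,
        param_names=names, sampled=tuple(n for i, n in enumerate(names) if mask[i]),
        draws=draws, loglik=ll, rhat=rhat, waic=waic, lppd=lppd, p_waic=p_waic,
        n_trials_used=len(kept), n_trials_excluded=n_all - len(kept),
        include_intercept=include_intercept, include_sigmoid=include_sigmoid,
        choice_only=choice_only, converged=converged,
        accept_rate={n: float(acc[i]) for i, n in enumerate(names) if mask[i]},
        seed=run_seed, records=kept)


def fit_choice_only(records, model: str, include_intercept: bool = True,
                    prior: PriorSpec | None = None, chains: int = 2,
                    samples: int = 10_000, burn: int = 5_000, seed: int = 0,
                    **kwargs) -> FitResult:
    """Bernoulli control model: P(distant) is the logistic of the drift
    predictor (attribute linear predictor, or temperature-scaled value
    difference); RTs are ignored."""
    return fit_ddm(records, model, include_intercept=include_intercept,
                   include_sigmoid=False, prior=prior, chains=chains,
                   samples=samples, burn=burn, seed=seed, choice_only=True,
                   **kwargs)
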