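"""Synthetic participant cohorts with known generating models.

This module stands in for deposited behavioral data: it samples participants
whose generating model (attribute-wise or option-wise) and parameters are
known, simulates their choices and response times through the diffusion
simulator under the task designs, and emulates the two-session drug study
with a configurable attenuation of each participant's dominant strategy.

Population parameter distributions are truncated normals chosen to produce
plausible behavior (mean RT between roughly 0.5 and 3 s, distant-choice
rates between 20 and 80% for the large majority of participants); they are
fully configurable via ``param_config``. Scales differ between task
batteries because attribute ranges do (euro cents vs hundreds of francs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .ddm import AttributeParams, OptionParams
from .task_design import (INTERPERSONAL, INTERTEMPORAL, Trial,
                          generate_drug_trials, generate_interpersonal_trials,
                          generate_intertemporal_trials)

__all__ = [
    "ChoiceRecord",
    "ParticipantSpec",
    "DEFAULT_PARAM_CONFIG",
    "sample_params",
    "sample_cohort",
    "simulate_behavior",
    "simulate_drug_cohort",
    "RESPONSE_WINDOW_S",
]

ATTRIBUTE = "attribute"
OPTION = "option"
MODELS = (ATTRIBUTE, OPTION)

#: choices must fall inside the stimulus presentation window; later responses
#: are treated as omissions
RESPONSE_WINDOW_S = 5.0

# (family, mean, sd, lower, upper); bounds are rejection bounds
DEFAULT_PARAM_CONFIG = {
    "intertemporal": {
        ATTRIBUTE: {
            "beta_intercept": ("normal", 0.5, 0.25, -2.0, 2.0),
            "beta_reward": ("normal", 0.4, 0.25, 0.05, 2.0),
            "beta_distance": ("normal", -0.012, 0.0035, -0.05, -0.001),
        },
        OPTION: {
            "beta_temperature": ("normal", 1.5, 0.5, 0.2, 5.0),
            "log_k": ("normal", -4.0, 1.0, -8.0, -1.0),
            "v_lim": ("normal", 2.0, 0.5, 0.5, 5.0),
        },
    },
    "interpersonal": {
        ATTRIBUTE: {
            "beta_intercept": ("normal", 0.3, 0.25, -2.0, 2.0),
            "beta_reward": ("normal", 0.4, 0.25, 0.05, 2.0),
            "beta_distance": ("normal", -0.03, 0.008, -0.1, -0.003),
        },
        OPTION: {
            "beta_temperature": ("normal", 1.2, 0.4, 0.2, 5.0),
            "log_k": ("normal", -4.0, 0.8, -8.0, -1.0),
            "v_lim": ("normal", 2.0, 0.5, 0.5, 5.0),
        },
    },
    "drug_intertemporal": {
        ATTRIBUTE: {
            "beta_intercept": ("normal", 0.3, 0.3, -2.0, 2.0),
            "beta_reward": ("normal", 0.02, 0.008, 0.003, 0.08),
            "beta_distance": ("normal", -0.03, 0.012, -0.1, -0.003),
        },
        OPTION: {
            "beta_temperature": ("normal", 0.05, 0.02, 0.005, 0.2),
            "log_k": ("normal", -3.5, 1.0, -7.0, -0.5),
            "v_lim": ("normal", 2.0, 0.5, 0.5, 5.0),
        },
    },
    "drug_interpersonal": {
        ATTRIBUTE: {
            "beta_intercept": ("normal", 0.3, 0.3, -2.0, 2.0),
            "beta_reward": ("normal", 0.35, 0.12, 0.05, 1.5),
            "beta_distance": ("normal", -0.02, 0.008, -0.08, -0.002),
        },
        OPTION: {
            "beta_temperature": ("normal", 0.8, 0.3, 0.1, 3.0),
            "log_k": ("normal", -4.0, 1.0, -8.0, -1.0),
            "v_lim": ("normal", 2.0, 0.5, 0.5, 5.0),
        },
    },
    # diffusion parameters shared by both model families
    "diffusion": {
        "alpha": ("normal", 1.5, 0.3, 0.5, 3.0),
        "zeta": ("normal", 0.5, 0.05, 0.2, 0.8),
        "tau": ("normal", 0.35, 0.08, 0.1, 0.7),
    },
}


@dataclass(frozen=True)
class ChoiceRecord:
    """One observed (or simulated) trial outcome.

    ``boundary`` is ``"upper"`` for a choice of the more distant option and
    ``"lower"`` for the closer option; omitted records (no response within
    the 5 s window) carry neither boundary nor rt.
    """

    participant: str
    trial: Trial
    boundary: str | None
    rt: float | None
    condition: str = "none"
    session: int = 0
    omitted: bool = False

    def __post_init__(self) -> None:
        if self.omitted:
            if self.boundary is not None or self.rt is not None:
                raise ValueError("omitted records carry no boundary or rt")
        else:
            if self.boundary not in ("upper", "lower"):
                raise ValueError(f"boundary must be 'upper' or 'lower', got {self.boundary!r}")
            if not (self.rt is not None and 0.0 < self.rt <= RESPONSE_WINDOW_S):
                raise ValueError(f"rt must be in (0, {RESPONSE_WINDOW_S}] s, got {self.rt!r}")


@dataclass(frozen=True)
class ParticipantSpec:
    """Ground truth for one simulated participant.

    Parameters for *both* model families are sampled per task; ``true_model``
    marks the dominant (generating) one. ``drug_effect`` scales how strongly
    a dopamine-antagonist session attenuates the dominant strategy (fraction
    of trials generated from the non-dominant model is
    ``drug_effect * effect_size``).
    """

    id: str
    true_model: str
    attribute_params: dict
    option_params: dict
    drug_effect: float = 0.0
    session_order: str = "placebo_first"

    def __post_init__(self) -> None:
        if self.true_model not in MODELS:
            raise ValueError(f"true_model must be one of {MODELS}")
        if not 0.0 <= self.drug_effect <= 1.0:
            raise ValueError("drug_effect must lie in [0, 1]")
        if self.session_order not in ("placebo_first", "drug_first"):
            raise ValueError("session_order must be 'placebo_first' or 'drug_first'")

    def params(self, task: str, model: str | None = None):
        model = model or self.true_model
        store = self.attribute_params if model == ATTRIBUTE else self.option_params
        return store[task]

    @property
    def params_intertemporal(self):
        return self.params(INTERTEMPORAL)

    @property
    def params_interpersonal(self):
        return self.params(INTERPERSONAL)


def _draw(rng, spec_tuple) -> float:
    family, mean, sd, lo, hi = spec_tuple
    if family != "normal":
        raise ValueError(f"unknown distribution family {family!r}")
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("rejection sampling failed; check distribution bounds")


def sample_params(model: str, design: str, rng, param_config=None):
    """Draw one participant's parameters for a model family and task design."""
    cfg = param_config or DEFAULT_PARAM_CONFIG
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    diff = {k: _draw(rng, v) for k, v in cfg["diffusion"].items()}
    drift = {k: _draw(rng, v) for k, v in cfg[design][model].items()}
    if model == ATTRIBUTE:
        return AttributeParams(**drift, **diff)
    return OptionParams(**drift, **diff)


def sample_cohort(n: int, attribute_fraction: float = 0.5, rng=None,
                  battery: str = "scanner", param_config=None) -> list[ParticipantSpec]:
    """Sample a cohort of participant specs with known generating models.

    ``attribute_fraction`` is the probability that a participant's dominant
    strategy is attribute-wise. ``battery`` selects the task designs:
    ``"scanner"`` (90-trial euro tasks) or ``"drug"`` (20/54-trial franc
    tasks, with counterbalanced session order and a per-participant
    ``drug_effect`` drawn uniformly from [0.5, 1]).
    """
    if not 0.0 <= attribute_fraction <= 1.0:
        raise ValueError("attribute_fraction must lie in [0, 1]")
    if battery not in ("scanner", "drug"):
        raise ValueError("battery must be 'scanner' or 'drug'")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    prefix = "" if battery == "scanner" else "drug_"
    specs = []
    for i in range(n):
        true_model = ATTRIBUTE if rng.random() < attribute_fraction else OPTION
        attr = {task: sample_params(ATTRIBUTE, prefix + task, rng, param_config)
                for task in (INTERTEMPORAL, INTERPERSONAL)}
        opt = {task: sample_params(OPTION, prefix + task, rng, param_config)
               for task in (INTERTEMPORAL, INTERPERSONAL)}
        drug_effect = float(rng.uniform(0.5, 1.0)) if battery == "drug" else 0.0
        order = ("drug_first", "placebo_first")[i % 2] if battery == "drug" else "placebo_first"
        specs.append(ParticipantSpec(id=f"p{i:03d}", true_model=true_model,
                                     attribute_params=attr, option_params=opt,
                                     drug_effect=drug_effect, session_order=order))
    return specs


def _drift_vector(trials, params) -> np.ndarray:
    from .ddm import drift_rates
    return drift_rates(trials, params)


def simulate_behavior(spec: ParticipantSpec, trials, contaminant_rate: float = 0.06,
                      rng=None, model: str | None = None, condition: str = "none",
                      session: int = 0, mixture_alt_prob: float = 0.0,
                      dt: float = 0.001) -> list[ChoiceRecord]:
    """Simulate one participant's choices and RTs on a list of trials.

    Each trial is simulated from the participant's generating model (or, with
    probability ``mixture_alt_prob``, from the non-dominant model -- the
    trial-level mixture used for the drug sessions). A ``contaminant_rate``
    fraction of trials is replaced by fast guesses (uniform 0.05-0.25 s RT,
    random boundary), emulating the fast anticipatory responses real data
    contain. Responses slower than the 5 s window become omissions.
    """
    if not trials:
        raise ValueError("trials must be nonempty")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    task = trials[0].task
    model = model or spec.true_model
    alt_model = OPTION if model == ATTRIBUTE else ATTRIBUTE
    n = len(trials)

    use_alt = rng.random(n) < mixture_alt_prob
    nu = np.empty(n)
    alpha = np.empty(n)
    zeta = np.empty(n)
    tau = np.empty(n)
    for which, mask in ((model, ~use_alt), (alt_model, use_alt)):
        if not mask.any():
            continue
        p = spec.params(task, which)
        sub = [t for t, m in zip(trials, mask) if m]
        nu[mask] = _drift_vector(sub, p)
        alpha[mask] = p.alpha
        zeta[mask] = p.zeta
        tau[mask] = p.tau

    seed = int(rng.integers(0, 2**31 - 1))
    boundary, rt = _kernels.simulate_walks(nu, alpha, zeta, tau, dt,
                                           RESPONSE_WINDOW_S + 3.0, seed)
    is_guess = rng.random(n) < contaminant_rate
    records = []
    for i, trial in enumerate(trials):
        if is_guess[i]:
            b = "upper" if rng.random() < 0.5 else "lower"
            records.append(ChoiceRecord(spec.id, trial, b,
                                        float(np.round(rng.uniform(0.05, 0.25), 3)),
                                        condition, session))
            continue
        if boundary[i] < 0 or rt[i] > RESPONSE_WINDOW_S:
            records.append(ChoiceRecord(spec.id, trial, None, None,
                                        condition, session, omitted=True))
            continue
        b = "upper" if boundary[i] == 1 else "lower"
        records.append(ChoiceRecord(spec.id, trial, b,
                                    float(np.round(max(rt[i], 0.001), 3)),
                                    condition, session))
    return records


def simulate_drug_cohort(n: int = 56, effect_size: float = 0.5, rng=None,
                         contaminant_rate: float = 0.06, param_config=None,
                         n_trials: tuple[int, int] = (20, 54),
                         attribute_fraction: float = 0.5,
                         temperature_scale: float = 1.0):
    """Simulate the two-session, within-subject drug study.

    Placebo sessions are generated wholly from each participant's dominant
    model; under the antagonist a fraction ``drug_effect * effect_size`` of
    trials is generated from the non-dominant model instead, realizing an
    attenuation of the dominant value-comparison strategy. Session order is
    counterbalanced; fresh trial sets are drawn for each session.

    ``temperature_scale`` multiplies every option-model inverse temperature
    under the antagonist (> 1 = more consistent choices under drug), for
    studying drug effects on choice consistency rather than strategy.

    Returns ``(records, specs)``.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    specs = sample_cohort(n, attribute_fraction, rng, battery="drug",
                          param_config=param_config)
    records = []
    for spec in specs:
        for session in (1, 2):
            if spec.session_order == "drug_first":
                condition = "amisulpride" if session == 1 else "placebo"
            else:
                condition = "placebo" if session == 1 else "amisulpride"
            on_drug = condition == "amisulpride"
            alt_prob = min(1.0, spec.drug_effect * effect_size) if on_drug else 0.0
            sim_spec = spec
            if on_drug and temperature_scale != 1.0:
                from dataclasses import replace as _replace
                scaled = {t: _replace(p, beta_temperature=p.beta_temperature
                                      * temperature_scale)
                          for t, p in spec.option_params.items()}
                sim_spec = _replace(spec, option_params=scaled)
            for task, ntr in zip((INTERTEMPORAL, INTERPERSONAL), n_trials):
                trials = generate_drug_trials(task, ntr, rng)
                records.extend(simulate_behavior(
                    sim_spec, trials, contaminant_rate, rng, condition=condition,
                    session=session, mixture_alt_prob=alt_prob))
    return records, specs


def scanner_trials(task: str, n: int = 90, rng=None) -> list[Trial]:
    """Convenience dispatcher for the scanner task designs."""
    if task == INTERTEMPORAL:
        return generate_intertemporal_trials(n, rng)
    return generate_interpersonal_trials(n, rng)
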