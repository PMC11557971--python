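"""Drift-diffusion machinery for cost-benefit choice.

Two families of drift-rate models are supported, both feeding the same
four-parameter Wiener diffusion (drift ``nu``, boundary separation ``alpha``,
relative starting bias ``zeta``, non-decision time ``tau``; diffusion
coefficient fixed at 1):

* **attribute-wise** -- the drift is a weighted sum of the attribute
  differences between the two options,
  ``nu = beta_intercept + beta_reward * reward_diff + beta_distance * distance_diff``;
* **option-wise** -- each option is first collapsed to a hyperbolically
  discounted subjective value ``SV = m / (1 + k * distance)``, the drift is
  ``nu' = beta_temperature * (SV_distant - SV_close)``, optionally squashed
  through a symmetric sigmoid with asymptote ``v_lim``.

The upper boundary always codes a choice of the more distant (larger-later /
shared) option, the lower boundary the closer option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._kernels import SERIES_EPS

__all__ = [
    "WienerParams",
    "AttributeParams",
    "OptionParams",
    "subjective_value",
    "attribute_drift",
    "option_drift",
    "drift_rates",
    "wiener_logpdf",
    "wiener_pdf",
    "upper_choice_probability",
    "simulate_trial",
    "simulate_trials",
]


def _check_diffusion(alpha: float, zeta: float, tau: float) -> None:
    if not alpha > 0:
        raise ValueError(f"boundary separation alpha must be > 0, got {alpha}")
    if not 0.0 < zeta < 1.0:
        raise ValueError(f"relative starting bias zeta must be in (0, 1), got {zeta}")
    if tau < 0:
        raise ValueError(f"non-decision time tau must be >= 0, got {tau}")


@dataclass(frozen=True)
class WienerParams:
    """Parameters of a single trial's diffusion (diffusion coefficient 1)."""

    nu: float
    alpha: float
    zeta: float = 0.5
    tau: float = 0.0

    def __post_init__(self) -> None:
        _check_diffusion(self.alpha, self.zeta, self.tau)


@dataclass(frozen=True)
class AttributeParams:
    """Attribute-wise drift weights plus the shared diffusion parameters."""

    beta_intercept: float
    beta_reward: float
    beta_distance: float
    alpha: float
    zeta: float = 0.5
    tau: float = 0.0
    include_intercept: bool = True

    def __post_init__(self) -> None:
        _check_diffusion(self.alpha, self.zeta, self.tau)

    def as_vector(self) -> np.ndarray:
        b0 = self.beta_intercept if self.include_intercept else 0.0
        return np.array([b0, self.beta_reward, self.beta_distance,
                         self.alpha, self.zeta, self.tau])


@dataclass(frozen=True)
class OptionParams:
    """Option-wise (discounted-value) drift parameters.

    ``log_k`` is the natural log of the hyperbolic discount rate; the rate
    itself, ``k = exp(log_k)``, is always positive.
    """

    beta_temperature: float
    log_k: float
    v_lim: float
    alpha: float
    zeta: float = 0.5
    tau: float = 0.0
    include_sigmoid: bool = True

    def __post_init__(self) -> None:
        _check_diffusion(self.alpha, self.zeta, self.tau)
        if self.beta_temperature < 0:
            raise ValueError("beta_temperature must be >= 0")
        if self.include_sigmoid and not self.v_lim > 0:
            raise ValueError("v_lim must be > 0 when the sigmoid transform is used")

    @property
    def k(self) -> float:
        return float(np.exp(self.log_k))

    def as_vector(self) -> np.ndarray:
        return np.array([self.beta_temperature, self.log_k, self.v_lim,
                         self.alpha, self.zeta, self.tau])


def subjective_value(magnitude, distance, k):
    """Hyperbolically discounted value ``magnitude / (1 + k * distance)``.

    ``distance`` is a delay in days (intertemporal) or a social distance
    (interpersonal); ``k`` is the individual discount rate.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    distance = np.asarray(distance, dtype=float)
    if np.any(distance < 0):
        raise ValueError("distance must be >= 0")
    if np.any(np.asarray(k) <= 0):
        raise ValueError("discount rate k must be > 0")
    out = magnitude / (1.0 + k * distance)
    return float(out) if out.ndim == 0 else out


def attribute_drift(trial, p: AttributeParams) -> float:
    """Drift of the attribute-wise model for one trial."""
    b0 = p.beta_intercept if p.include_intercept else 0.0
    return b0 + p.beta_reward * trial.reward_diff + p.beta_distance * trial.distance_diff


def option_drift(trial, p: OptionParams) -> float:
    """Drift of the option-wise model for one trial.

    Under the sigmoid transform the drift is strictly inside
    ``(-v_lim, v_lim)``.
    """
    dv = (subjective_value(trial.option_distant.magnitude, trial.option_distant.distance, p.k)
          - subjective_value(trial.option_close.magnitude, trial.option_close.distance, p.k))
    v_prime = p.beta_temperature * dv
    if not p.include_sigmoid:
        return v_prime
    return 2.0 * p.v_lim / (1.0 + np.exp(-v_prime)) - p.v_lim


def drift_rates(trials, params) -> np.ndarray:
    """Vector of drift rates over a list of trials for either model family."""
    if isinstance(params, AttributeParams):
        return np.array([attribute_drift(t, params) for t in trials])
    if isinstance(params, OptionParams):
        return np.array([option_drift(t, params) for t in trials])
    raise TypeError(f"unsupported parameter type {type(params)!r}")


def wiener_logpdf(rt, boundary, w: WienerParams):
    """Log density of (boundary, rt) under the Wiener first-passage model.

    ``boundary`` is ``"upper"`` (distant choice) or ``"lower"`` (closer
    choice). The upper-boundary density is the lower-boundary density under
    the reflection ``nu -> -nu``, ``zeta -> 1 - zeta``. Returns ``-inf`` for
    ``rt <= tau``.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    upper = boundary == "upper"
    rt = np.asarray(rt, dtype=float)
    if rt.ndim == 0:
        return _kernels.wiener_logpdf(float(rt), upper, w.nu, w.alpha, w.zeta,
                                      w.tau, SERIES_EPS)
    out = np.empty(rt.shape)
    for i, t in enumerate(rt.ravel()):
        out.flat[i] = _kernels.wiener_logpdf(float(t), upper, w.nu, w.alpha,
                                             w.zeta, w.tau, SERIES_EPS)
    return out


def wiener_pdf(rt, boundary, w: WienerParams):
    return np.exp(wiener_logpdf(rt, boundary, w))


def upper_choice_probability(w) -> float:
    """Closed-form probability of absorption at the upper (distant) boundary.

    ``(1 - exp(-2 nu alpha zeta)) / (1 - exp(-2 nu alpha))``, with limit
    ``zeta`` as ``nu -> 0``. Accepts a :class:`WienerParams` or explicit
    ``(nu, alpha, zeta)`` via keyword-free tuple unpacking.
    """
    if isinstance(w, WienerParams):
        nu, alpha, zeta = w.nu, w.alpha, w.zeta
    else:
        nu, alpha, zeta = w
    return float(_kernels.upper_prob(nu, alpha, zeta))


def simulate_trial(w: WienerParams, rng, dt: float = 0.001, t_max: float = 20.0):
    """Simulate one diffusion; returns ``(boundary, rt)``.

    ``boundary`` is ``"upper"``/``"lower"`` (or ``None`` if censored at
    ``t_max``); ``rt`` includes the non-decision time ``tau``.
    """
    boundary, rt = simulate_trials(np.array([w.nu]), w.alpha, w.zeta, w.tau,
                                   rng, dt=dt, t_max=t_max)
    b = {1: "upper", 0: "lower", -1: None}[int(boundary[0])]
    return b, float(rt[0])


def simulate_trials(nu, alpha, zeta, tau, rng, dt: float = 0.001,
                    t_max: float = 20.0):
    """Vectorized simulation, one walk per entry of ``nu``.

    ``alpha``, ``zeta``, ``tau`` may be scalars or arrays matching ``nu``.
    Returns ``(boundary int8 array, rt array)``; boundary is 1 upper / 0
    lower / -1 censored.
    """
    nu = np.ascontiguousarray(nu, dtype=float)
    n = nu.size
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (n,)).copy()
    zeta = np.broadcast_to(np.asarray(zeta, dtype=float), (n,)).copy()
    tau = np.broadcast_to(np.asarray(tau, dtype=float), (n,)).copy()
    seed = _seed_from(rng)
    return _kernels.simulate_walks(nu, alpha, zeta, tau, dt, t_max, seed)


def _seed_from(rng) -> int:
    """Derive a 31-bit integer seed from an int or numpy Generator."""
    if isinstance(rng, (int, np.integer)):
        return int(rng) % (2**31 - 1)
    if isinstance(rng, np.random.Generator):
        return int(rng.integers(0, 2**31 - 1))
    raise TypeError("rng must be an int seed or numpy.random.Generator")
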