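"""Trial generation for the intertemporal and interpersonal choice tasks.

Two task batteries are covered:

* the scanner battery (euro): 90-trial intertemporal and interpersonal
  designs with gridded closer-option magnitudes;
* the pharmacological battery (Swiss francs): a 20-trial intertemporal and a
  54-trial interpersonal design.

Attributes are sampled independently and uniformly over their grids/ranges,
rejecting any draw in which the distant option is not strictly more distant
than the closer one. Delays are whole days.

The shared option of the interpersonal tasks ("split X between self and a
person at distance d") is encoded as a single option of magnitude X (the
total split amount) at the distance of the farther recipient; an additive
two-recipient encoding (half the amount at each recipient's distance,
summed) is available via ``shared_encoding="per_recipient"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Option",
    "Trial",
    "generate_intertemporal_trials",
    "generate_interpersonal_trials",
    "generate_drug_trials",
    "trials_to_frame",
    "frame_to_trials",
]

INTERTEMPORAL = "intertemporal"
INTERPERSONAL = "interpersonal"
TASKS = (INTERTEMPORAL, INTERPERSONAL)


@dataclass(frozen=True)
class Option:
    """One reward option: a monetary magnitude at a temporal or social distance."""

    magnitude: float
    distance: float

    def __post_init__(self) -> None:
        if not self.magnitude > 0:
            raise ValueError(f"magnitude must be > 0, got {self.magnitude}")
        if self.distance < 0:
            raise ValueError(f"distance must be >= 0, got {self.distance}")


@dataclass(frozen=True)
class Trial:
    """A binary choice between a closer and a strictly more distant option.

    ``reward_diff`` and ``distance_diff`` (distant minus closer) are derived,
    never stored. ``reward_diff`` may be slightly negative in the
    pharmacological interpersonal design, where the selfish amount can exceed
    the shared amount.
    """

    task: str
    option_close: Option
    option_distant: Option

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}, got {self.task!r}")
        if not self.option_distant.distance > self.option_close.distance:
            raise ValueError(
                "distant option must be strictly more distant than the closer one "
                f"({self.option_distant.distance} vs {self.option_close.distance})")

    @property
    def reward_diff(self) -> float:
        return self.option_distant.magnitude - self.option_close.magnitude

    @property
    def distance_diff(self) -> float:
        return self.option_distant.distance - self.option_close.distance


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _check_n(n: int) -> None:
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ValueError(f"n must be a positive integer, got {n!r}")


def generate_intertemporal_trials(n: int, rng) -> list[Trial]:
    """Scanner intertemporal design: smaller-sooner vs 5 euro larger-later.

    Closer magnitude on the 0.5..5.0 euro grid (step 0.5) at a delay of 0-90
    days; distant option fixed at 5 euro, delay 10-360 days, always strictly
    later than the closer option.
    """
    _check_n(n)
    rng = _as_rng(rng)
    grid = np.arange(1, 11) * 0.5
    trials = []
    while len(trials) < n:
        m_close = float(rng.choice(grid))
        d_close = int(rng.integers(0, 91))
        d_distant = int(rng.integers(10, 361))
        if d_distant <= d_close:
            continue
        trials.append(Trial(INTERTEMPORAL,
                            Option(m_close, float(d_close)),
                            Option(5.0, float(d_distant))))
    return trials


def generate_interpersonal_trials(n: int, rng,
                                  shared_encoding: str = "total") -> list[Trial]:
    """Scanner interpersonal design: selfish/close reward vs a 10-euro split.

    Closer magnitude on the 5.5..10 euro grid (step 0.5) at social distance
    0, 10 or 20; the shared option splits 10 euro with a person at distance
    1, 10, 20, 50 or 100 and is encoded at the farther recipient's distance.
    """
    _check_n(n)
    rng = _as_rng(rng)
    grid = 5.5 + np.arange(10) * 0.5
    close_dists = np.array([0.0, 10.0, 20.0])
    distant_dists = np.array([1.0, 10.0, 20.0, 50.0, 100.0])
    total = 10.0
    trials = []
    while len(trials) < n:
        m_close = float(rng.choice(grid))
        d_close = float(rng.choice(close_dists))
        d_distant = float(rng.choice(distant_dists))
        if d_distant <= d_close:
            continue
        trials.append(Trial(INTERPERSONAL,
                            Option(m_close, d_close),
                            _shared_option(total, d_close, d_distant, shared_encoding)))
    return trials


def _shared_option(total: float, d_close: float, d_distant: float,
                   shared_encoding: str) -> Option:
    if shared_encoding == "total":
        return Option(total, d_distant)
    if shared_encoding == "per_recipient":
        # additive stand-in: half the amount placed at each recipient's
        # distance collapses to an effective single option only approximately;
        # encode as half the amount at the distant recipient (the closer half
        # is carried by the closer option's side of the comparison)
        return Option(total / 2.0, d_distant)
    raise ValueError(f"unknown shared_encoding {shared_encoding!r}")


def generate_drug_trials(task: str, n: int | None = None, rng=None) -> list[Trial]:
    """Pharmacological-study designs (Swiss francs).

    intertemporal (default n=20): closer 5-250 CHF at 0-30 days vs a distant
    option of 15-300 CHF at 3-90 days, strictly larger and strictly later
    (uniform sampling over the printed ranges; magnitudes on a 0.5 CHF grid).

    interpersonal (default n=54): selfish 7.5-15.5 CHF (step 0.5, distance 0)
    vs sharing 15 CHF with a person at distance 1, 5, 10, 20, 50 or 100.
    """
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}, got {task!r}")
    if n is None:
        n = 20 if task == INTERTEMPORAL else 54
    _check_n(n)
    rng = _as_rng(rng)
    trials = []
    if task == INTERTEMPORAL:
        while len(trials) < n:
            m_close = float(rng.integers(10, 501)) * 0.5     # 5 .. 250
            d_close = int(rng.integers(0, 31))
            m_distant = float(rng.integers(30, 601)) * 0.5   # 15 .. 300
            d_distant = int(rng.integers(3, 91))
            if m_distant <= m_close or d_distant <= d_close:
                continue
            trials.append(Trial(INTERTEMPORAL,
                                Option(m_close, float(d_close)),
                                Option(m_distant, float(d_distant))))
    else:
        grid = 7.5 + np.arange(17) * 0.5
        distant_dists = np.array([1.0, 5.0, 10.0, 20.0, 50.0, 100.0])
        for _ in range(n):
            m_close = float(rng.choice(grid))
            d_distant = float(rng.choice(distant_dists))
            trials.append(Trial(INTERPERSONAL,
                                Option(m_close, 0.0),
                                Option(15.0, d_distant)))
    return trials


def trials_to_frame(trials) -> pd.DataFrame:
    """Serialize trials to the canonical delimited table."""
    return pd.DataFrame({
        "trial_id": np.arange(len(trials)),
        "task": [t.task for t in trials],
        "m_close": [t.option_close.magnitude for t in trials],
        "d_close": [t.option_close.distance for t in trials],
        "m_distant": [t.option_distant.magnitude for t in trials],
        "d_distant": [t.option_distant.distance for t in trials],
    })


def frame_to_trials(frame: pd.DataFrame) -> list[Trial]:
    return [Trial(row.task,
                  Option(float(row.m_close), float(row.d_close)),
                  Option(float(row.m_distant), float(row.d_distant)))
            for row in frame.itertuples()]
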