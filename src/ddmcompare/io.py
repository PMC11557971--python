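"""File formats: the canonical choice table, ground-truth sidecars, configs.

Tables are comma-separated UTF-8 text with "." decimals; structured results
are JSON. RTs are stored in seconds to three decimals. The canonical choice
table has one row per trial:

    participant, task, condition, session, m_close, d_close, m_distant,
    d_distant, choice, rt_s

with ``choice`` in {closer, distant, omitted} (distant = upper boundary) and
an empty ``rt_s`` on omitted rows.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import ChoiceRecord, ParticipantSpec
from .ddm import AttributeParams, OptionParams
from .task_design import Option, Trial

__all__ = [
    "CHOICE_COLUMNS",
    "RunConfig",
    "records_to_frame",
    "frame_to_records",
    "write_choice_table",
    "read_choice_table",
    "write_ground_truth",
    "read_ground_truth",
    "fit_result_to_dict",
]

CHOICE_COLUMNS = ("participant", "task", "condition", "session", "m_close",
                  "d_close", "m_distant", "d_distant", "choice", "rt_s")


class TableValidationError(ValueError):
    """A malformed choice table; the message names the offending row/column."""


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        choice = "omitted" if r.omitted else ("distant" if r.boundary == "upper" else "closer")
        rows.append({
            "participant": r.participant, "task": r.trial.task,
            "condition": r.condition, "session": r.session,
            "m_close": r.trial.option_close.magnitude,
            "d_close": r.trial.option_close.distance,
            "m_distant": r.trial.option_distant.magnitude,
            "d_distant": r.trial.option_distant.distance,
            "choice": choice,
            "rt_s": np.nan if r.omitted else round(r.rt, 3)})
    return pd.DataFrame(rows, columns=list(CHOICE_COLUMNS))


def frame_to_records(frame: pd.DataFrame) -> list[ChoiceRecord]:
    missing = set(CHOICE_COLUMNS) - set(frame.columns)
    if missing:
        raise TableValidationError(f"missing column(s): {sorted(missing)}")
    records = []
    for i, row in enumerate(frame.itertuples()):
        def fail(col, msg):
            raise TableValidationError(f"row {i}, column {col!r}: {msg}")

        for col in ("m_close", "d_close", "m_distant", "d_distant"):
            v = getattr(row, col)
            if not np.isfinite(v):
                fail(col, f"non-numeric or missing value {v!r}")
        if row.choice not in ("closer", "distant", "omitted"):
            fail("choice", f"must be closer/distant/omitted, got {row.choice!r}")
        trial = Trial(row.task,
                      Option(float(row.m_close), float(row.d_close)),
                      Option(float(row.m_distant), float(row.d_distant)))
        if row.choice == "omitted":
            records.append(ChoiceRecord(str(row.participant), trial, None, None,
                                        str(row.condition), int(row.session),
                                        omitted=True))
            continue
        rt = row.rt_s
        if not (np.isfinite(rt) and rt > 0):
            fail("rt_s", f"non-omitted row needs rt > 0, got {rt!r}")
        boundary = "upper" if row.choice == "distant" else "lower"
        records.append(ChoiceRecord(str(row.participant), trial, boundary,
                                    float(rt), str(row.condition), int(row.session)))
    return records


def write_choice_table(records, path) -> Path:
    path = Path(path)
    records_to_frame(records).to_csv(path, index=False, float_format="%.3f")
    return path


def read_choice_table(path) -> list[ChoiceRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    return frame_to_records(frame)


def _params_to_dict(p) -> dict:
    d = dataclasses.asdict(p)
    d["_type"] = type(p).__name__
    return d


def _params_from_dict(d: dict):
    d = dict(d)
    cls = {"AttributeParams": AttributeParams, "OptionParams": OptionParams}[d.pop("_type")]
    return cls(**d)


def write_ground_truth(specs, path) -> Path:
    """JSON sidecar with every participant's generating model and parameters."""
    payload = []
    for s in specs:
        payload.append({
            "id": s.id, "true_model": s.true_model,
            "drug_effect": s.drug_effect, "session_order": s.session_order,
            "attribute_params": {t: _params_to_dict(p) for t, p in s.attribute_params.items()},
            "option_params": {t: _params_to_dict(p) for t, p in s.option_params.items()},
        })
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_ground_truth(path) -> list[ParticipantSpec]:
    payload = json.loads(Path(path).read_text())
    return [ParticipantSpec(
        id=d["id"], true_model=d["true_model"], drug_effect=d["drug_effect"],
        session_order=d["session_order"],
        attribute_params={t: _params_from_dict(p) for t, p in d["attribute_params"].items()},
        option_params={t: _params_from_dict(p) for t, p in d["option_params"].items()},
    ) for d in payload]


def fit_result_to_dict(fit, include_draws: bool = False) -> dict:
    """JSON-serializable summary of a fit (posterior draws optional)."""
    out = {
        "model": fit.model, "participant": fit.participant, "task": fit.task,
        "variant": {"include_intercept": fit.include_intercept,
                    "include_sigmoid": fit.include_sigmoid,
                    "choice_only": fit.choice_only},
        "posterior_mean": fit.posterior_mean(),
        "rhat": {k: (None if not np.isfinite(v) else float(v))
                 for k, v in fit.rhat.items()},
        "waic": fit.waic, "lppd": fit.lppd, "p_waic": fit.p_waic,
        "n_trials_used": fit.n_trials_used,
        "n_trials_excluded": fit.n_trials_excluded,
        "converged": fit.converged, "seed": fit.seed,
    }
    if include_draws:
        out["draws"] = fit.draws.tolist()
        out["param_names"] = list(fit.param_names)
    return out


@dataclasses.dataclass
class RunConfig:
    """Resolved settings for one pipeline run; written next to its outputs."""

    seed: int = 0
    n_participants: int = 35
    attribute_fraction: float = 0.5
    n_trials: int = 90
    contaminant_rate: float = 0.06
    exclusion_threshold_s: float = 0.250
    chains: int = 2
    samples: int = 10_000
    burn: int = 5_000
    include_intercept: bool = True
    include_sigmoid: bool = True
    cv_repeats: int = 10
    cv_test_frac: float = 0.1
    drug_n: int = 56
    drug_effect_size: float = 0.5
    out_dir: str = "."

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
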