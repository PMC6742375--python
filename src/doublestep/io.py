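"""Long-format CSV I/O for sessions, events and ground-truth tables.

Dialect: the samples file has one row per time sample
(participant, group, block, trial, condition_ms, direction, t_s, x_cm,
y_cm, z_cm); the events file has one row per trial with the event
timestamps and the touch endpoint.  ``condition_ms`` is empty for static
trials.  write -> read is the identity on every field to 1e-9.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .trajectory import Session, Trial
from .simulate import TrialTruth

logger = logging.getLogger(__name__)

SAMPLE_COLUMNS = ["participant", "group", "block", "trial", "condition_ms",
                  "direction", "t_s", "x_cm", "y_cm", "z_cm"]
EVENT_COLUMNS = ["participant", "group", "block", "trial", "condition_ms", "direction",
                 "target_onset_s", "reach_onset_s", "perturbation_s", "touch_s",
                 "touch_x_cm", "touch_y_cm"]
TRUTH_COLUMNS = ["participant", "block", "trial", "true_correction_onset_ms",
                 "is_artifact", "artifact_kind", "is_outlier"]

_FLOAT_FMT = "%.9f"


def session_to_frames(session: Session) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a session into (samples, events) DataFrames."""
    sample_rows, event_rows = [], []
    for tr in session:
        cond = "" if tr.condition_ms is None else int(tr.condition_ms)
        sample_rows.append(pd.DataFrame({
            "participant": tr.participant, "group": tr.group,
            "block": tr.block, "trial": tr.trial,
            "condition_ms": cond, "direction": tr.direction,
            "t_s": tr.t_s, "x_cm": tr.x_cm, "y_cm": tr.y_cm, "z_cm": tr.z_cm,
        }))
        event_rows.append({
            "participant": tr.participant, "group": tr.group,
            "block": tr.block, "trial": tr.trial,
            "condition_ms": cond, "direction": tr.direction,
            "target_onset_s": tr.target_onset_s, "reach_onset_s": tr.reach_onset_s,
            "perturbation_s": math.nan if tr.perturbation_s is None else tr.perturbation_s,
            "touch_s": tr.touch_s, "touch_x_cm": tr.touch_x_cm, "touch_y_cm": tr.touch_y_cm,
        })
    samples = (pd.concat(sample_rows, ignore_index=True) if sample_rows
               else pd.DataFrame(columns=SAMPLE_COLUMNS))
    events = pd.DataFrame(event_rows, columns=EVENT_COLUMNS)
    return samples, events


def write_session(session: Session, samples_path, events_path) -> None:
    samples, events = session_to_frames(session)
    samples.to_csv(samples_path, index=False, float_format=_FLOAT_FMT)
    events.to_csv(events_path, index=False, float_format=_FLOAT_FMT)


def _parse_condition(value) -> int | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return int(float(value))


def read_session(samples_path, events_path, sampling_rate: float = 240.0) -> Session:
    """Load a session, rejecting (with a diagnostic) trials that violate invariants.

    A trial with non-monotone sample times or inconsistent events is dropped
    and logged; remaining trials load normally.  An empty file yields an
    empty session with a warning.
    """
    try:
        samples = pd.read_csv(samples_path)
        events = pd.read_csv(events_path)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty session file", samples_path)
        return Session([], sampling_rate)
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    missing += [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing and not (samples.empty and events.empty):
        raise ValueError(f"{samples_path}: missing required columns {missing}")
    if events.empty:
        logger.warning("%s: empty session file", events_path)
        return Session([], sampling_rate)

    grouped = samples.groupby(["participant", "block", "trial"], sort=False)
    trials: list[Trial] = []
    for _, ev in events.iterrows():
        key = (ev["participant"], int(ev["block"]), int(ev["trial"]))
        try:
            chunk = grouped.get_group(key)
        except KeyError:
            logger.warning("trial %s: no samples found; rejected", key)
            continue
        cond = _parse_condition(ev["condition_ms"])
        pert = ev["perturbation_s"]
        trial = Trial(
            participant=str(ev["participant"]), group=str(ev["group"]),
            block=int(ev["block"]), trial=int(ev["trial"]),
            condition_ms=cond, direction=str(ev["direction"]),
            target_onset_s=float(ev["target_onset_s"]),
            reach_onset_s=float(ev["reach_onset_s"]),
            perturbation_s=None if pd.isna(pert) else float(pert),
            touch_s=float(ev["touch_s"]),
            touch_x_cm=float(ev["touch_x_cm"]), touch_y_cm=float(ev["touch_y_cm"]),
            t_s=chunk["t_s"].to_numpy(float),
            x_cm=chunk["x_cm"].to_numpy(float),
            y_cm=chunk["y_cm"].to_numpy(float),
            z_cm=chunk["z_cm"].to_numpy(float),
        )
        try:
            trial.validate()
        except ValueError as exc:
            logger.warning("rejected trial: %s", exc)
            continue
        trials.append(trial)
    return Session(trials, sampling_rate)


def truths_to_frame(truths: list[TrialTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(t, c) for c in TRUTH_COLUMNS} for t in truths],
        columns=TRUTH_COLUMNS,
    )


def write_ground_truth(truths: list[TrialTruth], path) -> None:
    truths_to_frame(truths).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_ground_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)
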