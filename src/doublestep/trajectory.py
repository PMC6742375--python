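"""Core data model, filtering, unit conversion, and data cleaning.

A :class:`Trial` holds the sampled finger trajectory of one reach together
with its event timestamps (target onset, reach onset = button release,
perturbation time, touch) and condition labels.  Samples cover the movement
epoch, from reach onset to touch, on the tracker's uniform time grid.

Cleaning proceeds in two stages, mirroring common practice with motion
tracker recordings: rule-based screening of apparatus/participant error
trials, then robust (median absolute deviation) outlier rejection on
per-trial summary measures.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

PERTURBATION_DIRECTIONS = ("left", "right")


@dataclass
class Trial:
    """One reach: sample stream, event timestamps, condition and endpoint."""

    participant: str
    group: str
    block: int
    trial: int
    condition_ms: float | None          # None = static, else 0 or 200 (ms post release)
    direction: str                      # "none" | "left" | "right"
    target_onset_s: float
    reach_onset_s: float
    perturbation_s: float | None        # absolute, perturbed trials only
    touch_s: float                      # NaN when the touch screen missed the response
    touch_x_cm: float
    touch_y_cm: float
    t_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    z_cm: np.ndarray

    @property
    def perturbed(self) -> bool:
        return self.condition_ms is not None

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.participant, self.block, self.trial)

    @property
    def n_samples(self) -> int:
        return len(self.t_s)

    def validate(self) -> None:
        n = self.n_samples
        if not (len(self.x_cm) == len(self.y_cm) == len(self.z_cm) == n):
            raise ValueError(f"trial {self.key}: ragged sample arrays")
        if n >= 2 and not np.all(np.diff(self.t_s) > 0):
            raise ValueError(f"trial {self.key}: sample times not strictly increasing")
        if self.perturbed:
            if self.direction not in PERTURBATION_DIRECTIONS:
                raise ValueError(f"trial {self.key}: perturbed trial lacks a direction")
            if self.perturbation_s is None:
                raise ValueError(f"trial {self.key}: perturbed trial lacks a perturbation time")
            expected = self.reach_onset_s + self.condition_ms / 1000.0
            if abs(self.perturbation_s - expected) > 1e-6:
                raise ValueError(
                    f"trial {self.key}: perturbation time {self.perturbation_s} "
                    f"inconsistent with reach onset + {self.condition_ms} ms"
                )

    def with_positions(self, x=None, y=None, z=None) -> "Trial":
        return replace(
            self,
            x_cm=self.x_cm if x is None else np.asarray(x, float),
            y_cm=self.y_cm if y is None else np.asarray(y, float),
            z_cm=self.z_cm if z is None else np.asarray(z, float),
        )


@dataclass
class Session:
    """A collection of trials sharing one tracker sampling rate."""

    trials: list[Trial]
    sampling_rate: float = 240.0
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def participants(self) -> list[str]:
        seen: dict[str, None] = {}
        for tr in self.trials:
            seen.setdefault(tr.participant, None)
        return list(seen)

    def select(self, predicate) -> "Session":
        return Session([t for t in self.trials if predicate(t)],
                       self.sampling_rate, dict(self.metadata))


@dataclass
class CleaningReport:
    """Counts of trials removed at each cleaning stage, with reasons."""

    n_input: int = 0
    removed_screening: list[tuple[tuple[str, int, int], str]] = field(default_factory=list)
    removed_mad: list[tuple[tuple[str, int, int], str]] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.removed_screening) + len(self.removed_mad)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed

    @property
    def fraction_removed(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0

    def removed_keys(self) -> set[tuple[str, int, int]]:
        return {k for k, _ in self.removed_screening} | {k for k, _ in self.removed_mad}

    def to_frame(self):
        import pandas as pd

        rows = [
            {"participant": k[0], "block": k[1], "trial": k[2], "stage": stage, "reason": reason}
            for stage, removed in (("screening", self.removed_screening), ("mad", self.removed_mad))
            for k, reason in removed
        ]
        return pd.DataFrame(rows, columns=["participant", "block", "trial", "stage", "reason"])


# ---------------------------------------------------------------------------
# Filtering and units

def lowpass_filter(series: np.ndarray, sampling_rate: float,
                   cutoff: float = 20.0, order: int = 4) -> np.ndarray:
    """Zero-phase (two-way) Butterworth low-pass filter of one position series.

    The filter is designed at the given order and applied forward and
    backward (``filtfilt``), doubling the effective magnitude order while
    cancelling phase delay, the standard treatment of kinematic data.
    """
    series = np.asarray(series, dtype=float)
    sos = signal.butter(order, cutoff, btype="low", fs=sampling_rate, output="sos")
    # padlen mirrors filtfilt's b/a default for a 2*order-coefficient filter
    padlen = 3 * (2 * order + 1)
    if len(series) <= padlen:
        raise ValueError(
            f"series of {len(series)} samples too short for zero-phase filtering "
            f"(needs > {padlen}); consider excluding the trial"
        )
    return signal.sosfiltfilt(sos, series, padlen=padlen)


def filter_trial(trial: Trial, sampling_rate: float,
                 cutoff: float = 20.0, order: int = 4) -> Trial:
    """Low-pass filter x, y and z of one trial independently."""
    return trial.with_positions(
        x=lowpass_filter(trial.x_cm, sampling_rate, cutoff, order),
        y=lowpass_filter(trial.y_cm, sampling_rate, cutoff, order),
        z=lowpass_filter(trial.z_cm, sampling_rate, cutoff, order),
    )


def cm_to_dva(offset_cm, viewing_distance_cm: float = 40.0):
    """Convert a screen offset in cm to degrees of visual angle.

    deg = atan(offset / viewing distance); odd and strictly increasing.
    """
    if viewing_distance_cm <= 0:
        raise ValueError("viewing_distance_cm must be > 0")
    return np.degrees(np.arctan(np.asarray(offset_cm, float) / viewing_distance_cm))


# ---------------------------------------------------------------------------
# Stage 1: rule-based error screening

def _screen_reason(trial: Trial, sampling_rate: float, max_gap_samples: int = 3) -> str | None:
    if not math.isfinite(trial.touch_s) or not math.isfinite(trial.touch_x_cm):
        return "missing touch response"
    if trial.reach_onset_s < trial.target_onset_s:
        return "premature start"
    if trial.n_samples < 2:
        return "zero-length trajectory"
    path = np.hypot(np.hypot(np.diff(trial.x_cm), np.diff(trial.y_cm)), np.diff(trial.z_cm))
    if float(path.sum()) == 0.0:
        return "zero-length trajectory"
    dt = 1.0 / sampling_rate
    if np.max(np.diff(trial.t_s)) > (max_gap_samples + 1) * dt * 1.125:
        return "sample gap"
    return None


def screen_error_trials(session: Session, max_gap_samples: int = 3
                        ) -> tuple[Session, CleaningReport]:
    """Remove apparatus-error and participant-error trials.

    Flags trials with a missing touch response, a reach initiated before
    target onset, more than ``max_gap_samples`` consecutive missing samples,
    or a zero-length trajectory.  Never raises.
    """
    report = CleaningReport(n_input=len(session))
    kept = []
    for trial in session:
        reason = _screen_reason(trial, session.sampling_rate, max_gap_samples)
        if reason is None:
            kept.append(trial)
        else:
            report.removed_screening.append((trial.key, reason))
            logger.info("screened trial %s: %s", trial.key, reason)
    return Session(kept, session.sampling_rate, dict(session.metadata)), report


# ---------------------------------------------------------------------------
# Stage 2: MAD outlier screening

MAD_CONSISTENCY = 1.4826  # scales the MAD to the SD of a normal distribution


def mad_outliers(values: Sequence[float], threshold: float = 3.0) -> np.ndarray:
    """Flag outliers by the median-absolute-deviation rule.

    A value v is flagged when |v - median| / (1.4826 * MAD) > threshold.
    With a degenerate MAD of zero, any value differing from the median is
    flagged.  Fewer than 4 values: nothing is flagged and a warning is
    issued, as the MAD is not meaningful at that sample size.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        warnings.warn("mad_outliers: fewer than 4 values; no outliers flagged", stacklevel=2)
        return np.zeros(len(values), dtype=bool)
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0.0:
        return values != med
    robust_z = np.abs(values - med) / (MAD_CONSISTENCY * mad)
    return robust_z > threshold


def mad_screen_trials(trial_table, variables: Iterable[str], threshold: float = 3.0,
                      by: Sequence[str] = ("participant", "condition_ms", "direction")):
    """Apply :func:`mad_outliers` per participant x condition cell.

    ``trial_table`` is a per-trial DataFrame carrying the grouping columns
    and the dependent variables.  Returns a boolean outlier mask aligned
    with the table's rows and a list of (key, reason) pairs.
    """
    import pandas as pd  # local: keeps numpy-only callers light

    mask = np.zeros(len(trial_table), dtype=bool)
    reasons: list[tuple[tuple[str, int, int], str]] = []
    grouped = trial_table.groupby(list(by), dropna=False, sort=False)
    for var in variables:
        for _, idx in grouped.groups.items():
            sub = trial_table.loc[idx, var]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                flags = mad_outliers(sub.to_numpy(), threshold)
            for row, flagged in zip(idx, flags):
                if flagged and not mask[trial_table.index.get_loc(row)]:
                    mask[trial_table.index.get_loc(row)] = True
                    key = (
                        trial_table.at[row, "participant"],
                        int(trial_table.at[row, "block"]),
                        int(trial_table.at[row, "trial"]),
                    )
                    reasons.append((key, f"MAD outlier on {var}"))
    return mask, reasons
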