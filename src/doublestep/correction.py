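"""Online-correction detection and path-offset measures.

The detector follows the envelope method for double-step reaching: the
horizontal traces of a participant's non-perturbed reaches, aligned at
reach onset, define a per-sample mean and a ±k·SD band (k = 1.5 by
default).  A perturbed trial elicits a detected correction when its
horizontal position leaves that band on the side of the perturbed target
and stays outside for a sustained run of samples.  The reported correction
latency is the start of that excursion relative to perturbation onset,
floored at the minimum visuomotor delay (80 ms): an excursion already in
progress when the scan opens is detected *at* the floor.

Path curvature is summarised by the linearity index L = A/B, where B is
the straight-line distance between reach start and end and A the maximum
perpendicular distance of the path from that line (L = 0 for a perfectly
straight path).  A is the maximum path offset (MPO); the time of the
offset-maximising sample, referenced to perturbation onset, is its latency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import Session, Trial

__all__ = [
    "Envelope",
    "CorrectionResult",
    "build_envelope",
    "build_envelopes",
    "envelope_key",
    "detect_correction",
    "path_linearity",
    "mpo_latency",
    "correction_frequency",
]


@dataclass
class Envelope:
    """Per-sample mean ± k·SD of horizontal position across non-perturbed trials.

    The time base is samples relative to reach onset on the tracker grid
    (``start_index`` <= 0 when the traces include a pre-movement baseline).
    Beyond the supported range the mean and SD are held at the nearest
    boundary values; during the reach, trials still in flight dominate, so
    the support count ``n`` is non-increasing in time.
    """

    grouping_key: tuple
    sampling_rate: float
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    k: float = 1.5
    start_index: int = 0   # grid index (samples from reach onset) of mean[0]

    def __len__(self) -> int:
        return len(self.mean)

    def aligned(self, rel_indices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Mean and SD at the given reach-onset-relative sample indices.

        Indices outside the supported range take the nearest boundary value
        (last values held beyond support).
        """
        pos = np.clip(np.asarray(rel_indices, int) - self.start_index, 0, len(self.mean) - 1)
        return self.mean[pos], self.sd[pos]

    def resampled(self, n_samples: int) -> tuple[np.ndarray, np.ndarray]:
        """Mean and SD on movement-epoch samples 0..n_samples-1 (last value held)."""
        return self.aligned(np.arange(n_samples))

    def bounds(self, n_samples: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        mean, sd = self.resampled(n_samples or len(self.mean))
        return mean - self.k * sd, mean + self.k * sd


@dataclass
class CorrectionResult:
    """Outcome of correction detection and path-offset measurement for one trial."""

    key: tuple
    detected: bool = False
    correction_latency_ms: float = math.nan   # ms from perturbation onset
    pre_deviated: bool = False     # already outside the band at perturbation
    opposite_crossing: bool = False  # sustained excursion away from the perturbed target
    L: float = math.nan            # path linearity A/B
    A_cm: float = math.nan         # maximum path offset
    B_cm: float = math.nan         # start-end distance
    mpo_latency_ms: float = math.nan  # ms from perturbation onset
    mpo_index: int = -1
    flags: list[str] = field(default_factory=list)


def envelope_key(trial: Trial, grouping: str = "participant_block") -> tuple:
    if grouping == "participant":
        return (trial.participant,)
    if grouping == "participant_block":
        return (trial.participant, trial.block)
    raise ValueError(f"unknown envelope grouping {grouping!r}")


def _rel_indices(trial: Trial, sampling_rate: float) -> np.ndarray:
    """Sample indices relative to reach onset on the tracker grid."""
    return np.rint((trial.t_s - trial.reach_onset_s) * sampling_rate).astype(int)


def build_envelope(trials: list[Trial], sampling_rate: float, k: float = 1.5,
                   min_support: int = 10, grouping_key: tuple = ()) -> Envelope:
    """Average the non-perturbed horizontal traces of one grouping unit.

    Trials are aligned at reach onset on the common sampling grid
    (pre-movement baseline samples included); at each sample, the mean and
    sample SD (ddof = 1) are taken over the trials covering it.  The
    envelope spans the contiguous region around reach onset supported by
    at least two trials.  Raises when fewer than ``min_support`` trials
    are available.
    """
    if len(trials) < min_support:
        raise ValueError(
            f"envelope {grouping_key or '(unnamed)'}: {len(trials)} non-perturbed "
            f"trials < minimum support {min_support}"
        )
    rel = [_rel_indices(t, sampling_rate) for t in trials]
    lo = min(int(r[0]) for r in rel)
    hi = max(int(r[-1]) for r in rel)
    stack = np.full((len(trials), hi - lo + 1), np.nan)
    for i, (t, r) in enumerate(zip(trials, rel)):
        stack[i, r - lo] = t.x_cm
    n = np.sum(~np.isnan(stack), axis=0)
    valid = n >= 2          # sample SD needs at least two trials covering it
    # contiguous supported region containing reach onset (index 0)
    i0 = -lo
    if not valid[i0]:
        raise ValueError(f"envelope {grouping_key}: no support at reach onset")
    a = i0
    while a > 0 and valid[a - 1]:
        a -= 1
    b = i0
    while b + 1 < len(valid) and valid[b + 1]:
        b += 1
    stack = stack[:, a:b + 1]
    n = n[a:b + 1]
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    return Envelope(grouping_key=grouping_key, sampling_rate=sampling_rate,
                    mean=mean, sd=sd, n=n, k=k, start_index=lo + a)


def build_envelopes(session: Session, k: float = 1.5, min_support: int = 10,
                    grouping: str = "participant_block") -> dict[tuple, Envelope]:
    """One envelope per grouping unit from a session's non-perturbed trials."""
    groups: dict[tuple, list[Trial]] = {}
    for trial in session:
        if not trial.perturbed:
            groups.setdefault(envelope_key(trial, grouping), []).append(trial)
    return {
        key: build_envelope(trials, session.sampling_rate, k, min_support, key)
        for key, trials in groups.items()
    }


def _sustained_runs(outside: np.ndarray, sustain: int) -> list[tuple[int, int]]:
    """(start, end) index pairs of runs of True at least ``sustain`` long."""
    runs = []
    start = None
    for i, flag in enumerate(outside):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= sustain:
                runs.append((start, i))
            start = None
    if start is not None and len(outside) - start >= sustain:
        runs.append((start, len(outside)))
    return runs


def detect_correction(trial: Trial, envelope: Envelope,
                      min_delay_ms: float = 80.0, sustain: int = 3,
                      result: CorrectionResult | None = None) -> CorrectionResult:
    """Envelope-threshold detection of the corrective response of one trial.

    The scan covers samples from perturbation + ``min_delay_ms`` to touch.
    Detection requires a scanned sample inside a run of at least
    ``sustain`` consecutive samples outside the band on the perturbed
    side; the latency is the start of that run relative to perturbation,
    floored at ``min_delay_ms``.  Sustained excursions on the opposite
    side are flagged but never counted.  Raises if the envelope does not
    cover the scan window.
    """
    if not trial.perturbed or trial.perturbation_s is None:
        raise ValueError(f"trial {trial.key}: correction detection needs a perturbed trial")
    res = result or CorrectionResult(key=trial.key)
    fs = envelope.sampling_rate
    dt = 1.0 / fs
    rel = _rel_indices(trial, fs)
    mean, sd = envelope.aligned(rel)
    pert_rel_s = trial.perturbation_s - trial.reach_onset_s
    # first stream position inside the scan window (pert + min_delay .. touch)
    scan_min_rel = int(math.ceil((pert_rel_s + min_delay_ms / 1000.0) * fs - 1e-9))
    scan_pos = int(np.searchsorted(rel, scan_min_rel))
    if scan_pos >= len(rel):
        raise ValueError(
            f"trial {trial.key}: scan window opens after the last sample "
            f"(envelope/trace undefined over the scan window)"
        )
    sign = {"right": 1.0, "left": -1.0}[trial.direction]
    deviation = sign * (trial.x_cm - mean)
    outside = deviation > envelope.k * sd
    opposite = (-deviation) > envelope.k * sd

    res.opposite_crossing = bool(_sustained_runs(opposite, sustain))
    pert_rel_smp = int(round(pert_rel_s * fs))   # perturbation is grid-aligned
    p_pert = int(np.searchsorted(rel, pert_rel_smp))
    for start, end in _sustained_runs(outside, sustain):
        if start < p_pert:
            if end > p_pert:
                # excursion already in progress at perturbation onset: the
                # deviation predates the stimulus, so no response is recorded
                res.pre_deviated = True
                break
            continue  # historic excursion, over before the perturbation
        if end <= scan_pos:
            continue  # excursion over before the scan window opens
        # integer sample arithmetic: identical crossings give identical latencies
        onset_ms = (int(rel[start]) - pert_rel_smp) * 1000.0 / fs
        res.detected = True
        res.correction_latency_ms = max(onset_ms, min_delay_ms)
        break
    return res


def path_linearity(x_cm, y_cm, z_cm=None, plane: str = "3d"
                   ) -> tuple[float, float, float, int]:
    """Path-linearity index of a sampled path: returns (L, A, B, argmax index).

    B is the Euclidean distance between the first and last sample, A the
    maximum perpendicular distance of any sample from the infinite line
    through them, and L = A/B (0 for a perfectly straight path).
    ``plane="horizontal"`` drops the vertical (y) coordinate.
    Degenerate paths (start == end) yield NaNs and index -1.
    """
    if plane == "horizontal":
        if z_cm is None:
            raise ValueError("horizontal plane needs z")
        pts = np.column_stack([np.asarray(x_cm, float), np.asarray(z_cm, float)])
    elif z_cm is None:
        pts = np.column_stack([np.asarray(x_cm, float), np.asarray(y_cm, float)])
    else:
        pts = np.column_stack([np.asarray(x_cm, float), np.asarray(y_cm, float),
                               np.asarray(z_cm, float)])
    if len(pts) < 3:
        raise ValueError("path_linearity needs at least 3 samples")
    chord = pts[-1] - pts[0]
    B = float(np.linalg.norm(chord))
    if B == 0.0:
        return math.nan, math.nan, 0.0, -1
    rel = pts - pts[0]
    u = chord / B
    # cross-product distance to the infinite start-end line (well conditioned
    # for near-collinear paths, unlike the Pythagorean form)
    if pts.shape[1] == 2:
        perp = np.abs(rel[:, 0] * u[1] - rel[:, 1] * u[0])
    else:
        perp = np.linalg.norm(np.cross(rel, u), axis=1)
    idx = int(np.argmax(perp))
    A = float(perp[idx])
    return A / B, A, B, idx


def trial_path_linearity(trial: Trial, plane: str = "3d") -> tuple[float, float, float, int]:
    """Linearity of the movement-epoch path (reach onset to touch)."""
    sel = trial.t_s >= trial.reach_onset_s - 1e-9
    return path_linearity(trial.x_cm[sel], trial.y_cm[sel], trial.z_cm[sel], plane)


def mpo_latency(trial: Trial, mpo_index: int) -> float:
    """Time of the maximum-path-offset sample, ms from perturbation onset."""
    if not trial.perturbed or trial.perturbation_s is None:
        raise ValueError(f"trial {trial.key}: MPO latency undefined for unperturbed trials")
    if mpo_index < 0:
        raise ValueError(f"trial {trial.key}: MPO undefined (degenerate path)")
    sel = trial.t_s >= trial.reach_onset_s - 1e-9
    t = trial.t_s[sel]
    return float((t[mpo_index] - trial.perturbation_s) * 1000.0)


def correction_frequency(results: pd.DataFrame) -> pd.DataFrame:
    """Percentage of perturbed trials with a detected correction, per cell.

    ``results`` carries one row per perturbed trial with columns
    group, condition_ms, direction, detected.  Cells with no trials are
    reported as missing (NaN), never as zero.
    """
    table = (
        results
        .groupby(["group", "condition_ms", "direction"], observed=True)["detected"]
        .agg(percent=lambda d: 100.0 * d.mean(), n="size")
        .reset_index()
    )
    wide = table.pivot_table(index="group", columns=["condition_ms", "direction"],
                             values="percent", dropna=False)
    wide = wide.sort_index(axis=1)
    return wide
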