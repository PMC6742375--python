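"""Per-trial temporal and spatial dependent variables.

Reach latency (target onset to button release), reach duration (release to
touch), tangential speed by central differences, peak velocity, the
acceleration/deceleration split at peak speed, and absolute horizontal
endpoint accuracy in degrees of visual angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trajectory import Trial, cm_to_dva


@dataclass
class KinematicProfile:
    speed_cm_s: np.ndarray
    peak_velocity_cm_s: float
    time_of_peak_ms: float        # ms from reach onset
    acceleration_time_ms: float
    deceleration_time_ms: float
    reach_latency_ms: float
    reach_duration_ms: float
    degenerate: bool              # peak speed at the first or last sample


def compute_speed(t_s: np.ndarray, x_cm: np.ndarray, y_cm: np.ndarray,
                  z_cm: np.ndarray, mode: str = "3d") -> np.ndarray:
    """Tangential speed (cm/s) by central differences, one-sided at the ends.

    ``mode="3d"`` uses the full 3D path; ``mode="horizontal"`` restricts to
    the horizontal (x, z) plane.
    """
    t_s = np.asarray(t_s, float)
    if len(t_s) < 3:
        raise ValueError("compute_speed needs at least 3 samples")
    comps = [x_cm, z_cm] if mode == "horizontal" else [x_cm, y_cm, z_cm]
    v_sq = None
    for c in comps:
        dc = np.gradient(np.asarray(c, float), t_s)
        v_sq = dc**2 if v_sq is None else v_sq + dc**2
    return np.sqrt(v_sq)


def kinematic_profile(trial: Trial, mode: str = "3d") -> KinematicProfile:
    """Temporal landmarks of one (cleaned, filtered) trial.

    Peak-velocity ties are broken by the earliest sample.  A profile whose
    speed peaks at the first or last sample is flagged degenerate rather
    than dropped.
    """
    speed = compute_speed(trial.t_s, trial.x_cm, trial.y_cm, trial.z_cm, mode)
    i_peak = int(np.argmax(speed))          # argmax returns the earliest maximum
    peak = float(speed[i_peak])
    t_peak_ms = (trial.t_s[i_peak] - trial.reach_onset_s) * 1000.0
    latency_ms = (trial.reach_onset_s - trial.target_onset_s) * 1000.0
    duration_ms = (trial.touch_s - trial.reach_onset_s) * 1000.0
    return KinematicProfile(
        speed_cm_s=speed,
        peak_velocity_cm_s=peak,
        time_of_peak_ms=t_peak_ms,
        acceleration_time_ms=t_peak_ms,
        deceleration_time_ms=duration_ms - t_peak_ms,
        reach_latency_ms=latency_ms,
        reach_duration_ms=duration_ms,
        degenerate=i_peak in (0, len(speed) - 1),
    )


def absolute_x_accuracy(trial: Trial, final_target_x_cm: float,
                        viewing_distance_cm: float = 40.0) -> float:
    """|horizontal touch error| in degrees of visual angle.

    On perturbed trials the final (displaced) target location is the
    reference, whether or not a correction occurred.
    """
    if not math.isfinite(trial.touch_x_cm):
        raise ValueError(f"trial {trial.key}: missing touch (should have been screened)")
    return float(abs(cm_to_dva(trial.touch_x_cm - final_target_x_cm, viewing_distance_cm)))
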