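"""Synthetic double-step reach sessions with ground-truth labels.

The generator emulates motion-tracker recordings of centre-out pointing
movements at 240 Hz.  Each reach follows a smooth point-to-point primitive
(a Beta-shaped speed profile whose symmetric default is exactly the
minimum-jerk law ``s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5``).  On perturbed
trials that elicit a correction, a second minimum-jerk submovement toward
the displaced target is superimposed on the horizontal coordinate, starting
at perturbation time plus a drawn correction latency.  Sensor noise,
per-trial constant lateral offsets, apparatus-error trials and
behavioural-outlier trials are injected at configurable rates, and every
injected feature is recorded in a ground-truth table for validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal, special

from .config import GeneratorConfig, GroupParams
from .trajectory import Session, Trial

__all__ = [
    "TrialParams",
    "TrialTruth",
    "minimum_jerk",
    "beta_position_profile",
    "generate_trial",
    "generate_session",
]


def minimum_jerk(tau):
    """Minimum-jerk position fraction s(tau) on [0, 1], clamped outside."""
    tau = np.clip(np.asarray(tau, dtype=float), 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def beta_position_profile(tau, accel_fraction: float = 0.5):
    """Position fraction of a reach whose speed is Beta(3, b)-shaped.

    ``accel_fraction`` is the fraction of movement time before peak speed;
    0.5 recovers the minimum-jerk profile exactly (Beta(3, 3) speed).
    """
    b = 2.0 / accel_fraction - 1.0
    tau = np.clip(np.asarray(tau, dtype=float), 0.0, 1.0)
    return special.betainc(3.0, b, tau)


@dataclass
class TrialParams:
    """Fully drawn per-trial parameters handed to :func:`generate_trial`."""

    participant: str
    group: str
    block: int
    trial: int
    condition_ms: int | None            # None = static
    direction: str                      # "none" | "left" | "right"
    foreperiod_ms: float
    reach_latency_ms: float
    reach_duration_ms: float
    accel_fraction: float = 0.5
    correction: bool = False
    correction_latency_ms: float = math.nan   # ms from perturbation
    submovement_duration_ms: float = math.nan
    start_offset_cm: float = 0.0
    artifact: str | None = None         # None | missing_touch | premature_start | sample_gap
    outlier: bool = False


@dataclass
class TrialTruth:
    """Ground-truth labels for one generated trial."""

    participant: str
    block: int
    trial: int
    true_correction_onset_ms: float     # ms from perturbation; NaN if none injected
    is_artifact: bool
    artifact_kind: str
    is_outlier: bool

    @property
    def key(self):
        return (self.participant, self.block, self.trial)


def _correlated_noise(n: int, sd: float, sampling_rate: float, cutoff: float,
                      rng: np.random.Generator) -> np.ndarray:
    """White Gaussian noise, zero-phase low-pass filtered at ``cutoff``."""
    white = rng.normal(0.0, sd, size=n)
    if cutoff <= 0 or cutoff >= sampling_rate / 2:
        return white
    sos = signal.butter(4, cutoff, btype="low", fs=sampling_rate, output="sos")
    padlen = 3 * 9
    if n <= padlen:        # trajectory too short to filter; keep white noise
        return white
    return signal.sosfiltfilt(sos, white, padlen=padlen)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  trunc: float = 2.0) -> float:
    """Normal draw truncated at ±``trunc`` SD (bounded reaction-time model)."""
    if sd == 0:
        return mean
    while True:
        z = rng.normal()
        if abs(z) <= trunc:
            return mean + sd * z


def generate_trial(config: GeneratorConfig, params: TrialParams,
                   rng: np.random.Generator, max_redraws: int = 100
                   ) -> tuple[Trial, TrialTruth]:
    """Build one trial's trajectory, events and ground truth from drawn parameters.

    The reach starts at (start offset, 0, viewing distance) and lands on the
    screen plane (z = 0).  A corrective submovement, when present, adds a
    minimum-jerk lateral displacement toward the perturbed target; the touch
    occurs when both movements have completed.  Raises ``RuntimeError`` if a
    consistent timing draw cannot be found within ``max_redraws``.
    """
    fs = config.sampling_rate
    dt = 1.0 / fs
    group: GroupParams = config.groups[params.group]

    duration_s = params.reach_duration_ms / 1000.0
    redraws = 0
    while duration_s <= 3 * dt:
        if redraws >= max_redraws:
            raise RuntimeError(f"trial {params.trial}: redraw budget exhausted (duration)")
        duration_s = _trunc_normal(rng, *group.reach_duration_ms, config.trunc_sd) / 1000.0
        redraws += 1

    corr_start_rel = math.nan
    sub_duration_s = math.nan
    if params.correction:
        corr_latency_s = params.correction_latency_ms / 1000.0
        sub_duration_s = params.submovement_duration_ms / 1000.0
        redraws = 0
        while not (corr_latency_s > 0 and sub_duration_s > 3 * dt):
            if redraws >= max_redraws:
                raise RuntimeError(f"trial {params.trial}: redraw budget exhausted (correction)")
            corr_latency_s = _trunc_normal(
                rng, *group.correction_latency_ms[params.condition_ms], config.trunc_sd) / 1000.0
            sub_duration_s = _trunc_normal(
                rng, *group.submovement_duration_ms, config.trunc_sd) / 1000.0
            redraws += 1
        corr_start_rel = params.condition_ms / 1000.0 + corr_latency_s

    # recorded epoch: pre-movement baseline (finger resting on the start key,
    # from target onset) followed by the reach, on a grid aligned at reach onset
    end_rel = duration_s
    if params.correction:
        end_rel = max(end_rel, corr_start_rel + sub_duration_s)
    n_move = int(math.ceil(end_rel / dt - 1e-9)) + 1  # last sample at/just past completion
    n_pre = max(0, int(math.floor(params.reach_latency_ms / 1000.0 / dt)))
    t_rel = np.arange(-n_pre, n_move) * dt
    n = n_pre + n_move

    # primary reach: x constant, y to the elevated target, z to the screen
    frac = beta_position_profile(t_rel / duration_s, params.accel_fraction)
    x = np.full(n, params.start_offset_cm)
    y = config.target_y_cm * frac
    z = config.viewing_distance * (1.0 - frac)

    if params.correction:
        dx = config.perturbed_target_x_cm(params.direction)
        x = x + dx * minimum_jerk((t_rel - corr_start_rel) / sub_duration_s)

    if config.noise_sd > 0:
        x = x + _correlated_noise(n, config.noise_sd, fs, config.noise_cutoff, rng)
        y = y + _correlated_noise(n, config.noise_sd, fs, config.noise_cutoff, rng)
        z = z + _correlated_noise(n, config.noise_sd, fs, config.noise_cutoff, rng)

    target_onset_s = params.foreperiod_ms / 1000.0
    reach_onset_s = target_onset_s + params.reach_latency_ms / 1000.0
    perturbation_s = None
    if params.condition_ms is not None:
        perturbation_s = reach_onset_s + params.condition_ms / 1000.0
    touch_s = reach_onset_s + t_rel[-1]
    touch_x, touch_y = float(x[-1]), float(y[-1])

    t_abs = reach_onset_s + t_rel

    if params.artifact == "missing_touch":
        touch_s = math.nan
        touch_x = touch_y = math.nan
    elif params.artifact == "sample_gap":
        gap_len = 5  # > 3 consecutive missing samples
        if n > gap_len + 8:
            start = int(rng.integers(4, n - gap_len - 4))
            keep = np.ones(n, dtype=bool)
            keep[start:start + gap_len] = False
            t_abs, x, y, z = t_abs[keep], x[keep], y[keep], z[keep]

    trial = Trial(
        participant=params.participant,
        group=params.group,
        block=params.block,
        trial=params.trial,
        condition_ms=params.condition_ms,
        direction=params.direction,
        target_onset_s=target_onset_s,
        reach_onset_s=reach_onset_s,
        perturbation_s=perturbation_s,
        touch_s=touch_s,
        touch_x_cm=touch_x,
        touch_y_cm=touch_y,
        t_s=t_abs,
        x_cm=x,
        y_cm=y,
        z_cm=z,
    )
    truth = TrialTruth(
        participant=params.participant,
        block=params.block,
        trial=params.trial,
        true_correction_onset_ms=corr_latency_s * 1000.0 if params.correction else math.nan,
        is_artifact=params.artifact is not None,
        artifact_kind=params.artifact or "",
        is_outlier=params.outlier,
    )
    return trial, truth


def _block_conditions(config: GeneratorConfig, rng: np.random.Generator
                      ) -> list[tuple[int | None, str]]:
    """Exact per-block condition labels, randomly interleaved."""
    tpb = config.trials_per_block
    n_static = int(round(config.trial_mix[0] * tpb))
    n_left = int(round(config.trial_mix[1] * tpb))
    n_right = tpb - n_static - n_left
    labels: list[tuple[int | None, str]] = [(None, "none")] * n_static
    times = list(config.perturbation_times)
    for direction, count in (("left", n_left), ("right", n_right)):
        per_time = count // len(times)
        extra = count - per_time * len(times)
        for i, pt in enumerate(times):
            labels += [(int(pt), direction)] * (per_time + (1 if i < extra else 0))
    order = rng.permutation(len(labels))
    return [labels[i] for i in order]


def _draw_params(config: GeneratorConfig, pid: str, group_name: str, block: int,
                 trial_idx: int, cond: int | None, direction: str,
                 rng: np.random.Generator) -> TrialParams:
    group = config.groups[group_name]
    latency = _trunc_normal(rng, *group.reach_latency_ms, config.trunc_sd)
    duration = _trunc_normal(rng, *group.reach_duration_ms, config.trunc_sd)

    offset = rng.normal(0.0, config.start_offset_sd)
    if config.start_offset_outlier_rate > 0 and rng.random() < config.start_offset_outlier_rate:
        offset = rng.normal(0.0, config.start_offset_outlier_sd)

    correction = False
    corr_latency = math.nan
    sub_duration = math.nan
    if cond is not None:
        p = group.correction_probability.get((cond, direction), 0.0)
        if p > 0 and rng.random() < p:
            correction = True
            corr_latency = _trunc_normal(rng, *group.correction_latency_ms[cond],
                                         config.trunc_sd)
            sub_duration = _trunc_normal(rng, *group.submovement_duration_ms,
                                         config.trunc_sd)

    artifact = None
    if config.artifact_rate > 0 and rng.random() < config.artifact_rate:
        artifact = ("missing_touch", "premature_start", "sample_gap")[int(rng.integers(3))]
    outlier = False
    if artifact is None and config.behavioral_outlier_rate > 0 \
            and rng.random() < config.behavioral_outlier_rate:
        outlier = True
        latency = group.reach_latency_ms[0] + \
            config.outlier_latency_shift_sd * group.reach_latency_ms[1]
    if artifact == "premature_start":
        latency = -abs(_trunc_normal(rng, 50.0, 20.0, config.trunc_sd))

    return TrialParams(
        participant=pid, group=group_name, block=block, trial=trial_idx,
        condition_ms=cond, direction=direction,
        foreperiod_ms=rng.uniform(*config.foreperiod_ms),
        reach_latency_ms=latency, reach_duration_ms=duration,
        accel_fraction=group.accel_fraction,
        correction=correction, correction_latency_ms=corr_latency,
        submovement_duration_ms=sub_duration,
        start_offset_cm=offset, artifact=artifact, outlier=outlier,
    )


def generate_session(config: GeneratorConfig, seed: int | None = None
                     ) -> tuple[Session, list[TrialTruth]]:
    """Generate a full multi-block session for every configured participant.

    Deterministic under a fixed seed (``seed`` overrides ``config.seed``).
    Trial types are exactly counterbalanced within each block and randomly
    interleaved; contaminant trials are injected at the configured rates.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    trials: list[Trial] = []
    truths: list[TrialTruth] = []
    for pid, group_name in config.participants:
        for block in range(1, config.blocks + 1):
            conditions = _block_conditions(config, rng)
            for idx, (cond, direction) in enumerate(conditions, start=1):
                params = _draw_params(config, pid, group_name, block, idx,
                                      cond, direction, rng)
                trial, truth = generate_trial(config, params, rng)
                trials.append(trial)
                truths.append(truth)
    session = Session(trials, sampling_rate=config.sampling_rate,
                      metadata={"generator": "doublestep.simulate",
                                "seed": config.seed if seed is None else seed})
    return session, truths
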