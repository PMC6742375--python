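"""Configuration objects for the simulator and the analysis pipeline.

All defaults mirror the double-step pointing protocol the package targets:
a Polhemus-style tracker at 240 Hz, a touch screen at 40 cm viewing
distance, an initial target 4.5 degrees above fixation, lateral target
perturbations of 10 degrees scheduled 0 or 200 ms after reach onset on
half of the trials (25% left, 25% right), six blocks of 80 trials, and a
550 ms reach-duration time pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import yaml

DEG = math.pi / 180.0


def deg_to_cm(angle_deg: float, viewing_distance_cm: float = 40.0) -> float:
    """Convert an eccentricity in degrees of visual angle to cm on the screen."""
    return viewing_distance_cm * math.tan(angle_deg * DEG)


@dataclass
class GroupParams:
    """Per-group timing and correction parameters.

    Means/SDs are in milliseconds.  Draws from these distributions are
    truncated at ``trunc_sd`` standard deviations, reflecting the bounded
    range of compliant reaction times and keeping robust outlier screening
    well calibrated.
    """

    reach_latency_ms: tuple[float, float] = (266.0, 50.0)
    reach_duration_ms: tuple[float, float] = (496.3, 45.0)
    # correction latency (ms from perturbation) per perturbation time condition
    correction_latency_ms: Mapping[int, tuple[float, float]] = field(
        default_factory=lambda: {0: (330.0, 40.0), 200: (297.0, 40.0)}
    )
    # probability of producing a corrective submovement, per (condition, direction)
    correction_probability: Mapping[tuple[int, str], float] = field(
        default_factory=lambda: {
            (0, "left"): 1.0,
            (0, "right"): 1.0,
            (200, "left"): 0.72,
            (200, "right"): 0.66,
        }
    )
    # corrective submovement duration, ms
    submovement_duration_ms: tuple[float, float] = (260.0, 40.0)
    # fraction of the reach spent accelerating (0.5 = symmetric minimum jerk)
    accel_fraction: float = 0.5

    def validate(self) -> None:
        for name in ("reach_latency_ms", "reach_duration_ms", "submovement_duration_ms"):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd < 0:
                raise ValueError(f"{name}: mean must be > 0 and SD >= 0, got {(mean, sd)}")
        for cond, (mean, sd) in self.correction_latency_ms.items():
            if mean <= 0 or sd < 0:
                raise ValueError(f"correction_latency_ms[{cond}]: invalid {(mean, sd)}")
        for key, p in self.correction_probability.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"correction_probability[{key}] = {p} outside [0, 1]")
        if not 0.0 < self.accel_fraction < 1.0:
            raise ValueError("accel_fraction must lie in (0, 1)")


#: Correction probabilities observed in the study the defaults emulate
#: (percentage of perturbed trials eliciting a correction, by condition x direction).
YOUNGER_CORRECTION_PROBABILITY = {
    (0, "left"): 1.00,
    (0, "right"): 1.00,
    (200, "left"): 0.72,
    (200, "right"): 0.66,
}
OLDER_CORRECTION_PROBABILITY = {
    (0, "left"): 0.91,
    (0, "right"): 0.92,
    (200, "left"): 0.59,
    (200, "right"): 0.48,
}


def default_groups() -> dict[str, GroupParams]:
    """Default younger/older parameter sets.

    The older group is slower to start (+28 ms latency), slower overall
    (+36 ms duration), spends ~37 ms longer decelerating, and corrects
    less often.
    """
    younger = GroupParams(
        correction_probability=dict(YOUNGER_CORRECTION_PROBABILITY),
    )
    older = GroupParams(
        reach_latency_ms=(294.0, 60.0),
        reach_duration_ms=(532.3, 55.0),
        correction_probability=dict(OLDER_CORRECTION_PROBABILITY),
        accel_fraction=0.4643,
    )
    return {"younger": younger, "older": older}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic double-step session generator."""

    sampling_rate: float = 240.0            # Hz
    viewing_distance: float = 40.0          # cm
    target_elevation: float = 4.5           # deg above fixation
    perturbation_eccentricity: float = 10.0  # deg left/right of centre
    perturbation_times: Sequence[int] = (0, 200)   # ms post reach onset
    trial_mix: tuple[float, float, float] = (0.5, 0.25, 0.25)  # static/left/right
    trials_per_block: int = 80
    blocks: int = 6
    foreperiod_ms: tuple[float, float] = (500.0, 1000.0)  # uniform variable delay
    participants: Sequence[tuple[str, str]] = (("y01", "younger"), ("o01", "older"))
    groups: Mapping[str, GroupParams] = field(default_factory=default_groups)

    # positional sensor noise: white Gaussian, low-pass filtered
    noise_sd: float = 0.05                  # cm, per axis, before filtering
    noise_cutoff: float = 10.0              # Hz

    # per-trial constant lateral offset (sensor mounting / start placement);
    # the dominant across-trial variability of the horizontal trace
    start_offset_sd: float = 0.25           # cm
    start_offset_outlier_rate: float = 0.0  # optional gross-misplacement mixture
    start_offset_outlier_sd: float = 1.0    # cm, gross component

    # contaminant trials
    artifact_rate: float = 0.05             # apparatus/participant error trials
    behavioral_outlier_rate: float = 0.05   # extreme-latency trials
    outlier_latency_shift_sd: float = 8.0   # latency shift in units of the latency SD

    trunc_sd: float = 2.0                   # truncation of timing draws
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.viewing_distance <= 0:
            raise ValueError("viewing_distance must be > 0")
        if abs(sum(self.trial_mix) - 1.0) > 1e-9:
            raise ValueError(f"trial_mix must sum to 1, got {self.trial_mix}")
        if any(p < 0 for p in self.trial_mix):
            raise ValueError("trial_mix proportions must be >= 0")
        if self.trials_per_block <= 0 or self.blocks <= 0:
            raise ValueError("trials_per_block and blocks must be positive")
        for name in ("noise_sd", "start_offset_sd", "start_offset_outlier_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("artifact_rate", "behavioral_outlier_rate", "start_offset_outlier_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.foreperiod_ms[0] > self.foreperiod_ms[1]:
            raise ValueError("foreperiod_ms bounds out of order")
        if not self.participants:
            raise ValueError("at least one participant required")
        for pid, group in self.participants:
            if group not in self.groups:
                raise ValueError(f"participant {pid!r} references unknown group {group!r}")
        for gp in self.groups.values():
            gp.validate()

    # geometry helpers -------------------------------------------------
    @property
    def target_y_cm(self) -> float:
        return deg_to_cm(self.target_elevation, self.viewing_distance)

    def perturbed_target_x_cm(self, direction: str) -> float:
        sign = {"left": -1.0, "right": 1.0}[direction]
        return sign * deg_to_cm(self.perturbation_eccentricity, self.viewing_distance)


@dataclass
class DetectorConfig:
    """Envelope-based correction-detector settings."""

    k_sd: float = 1.5            # envelope half-width, in SD units
    min_delay_ms: float = 80.0   # minimum visuomotor delay (detection floor)
    sustain: int = 3             # consecutive samples required outside the envelope
    min_support: int = 10        # minimum non-perturbed trials per envelope
    grouping: str = "participant_block"  # or "participant"


@dataclass
class PipelineConfig:
    """Union of all analysis-stage settings (single source of truth for the CLI)."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    filter_cutoff: float = 20.0   # Hz, two-way Butterworth
    filter_order: int = 4
    mad_threshold: float = 3.0
    mad_variables: tuple[str, ...] = ("reach_latency_ms",)
    speed_mode: str = "3d"        # or "horizontal"
    seed: int = 0


# ---------------------------------------------------------------------------
# YAML round-trip

def _groups_from_dict(d: Mapping) -> dict[str, GroupParams]:
    groups = {}
    for name, g in d.items():
        g = dict(g)
        if "correction_latency_ms" in g:
            g["correction_latency_ms"] = {
                int(k): tuple(v) for k, v in g["correction_latency_ms"].items()
            }
        if "correction_probability" in g:
            cp = {}
            for k, v in g["correction_probability"].items():
                cond, direction = k.split("_") if isinstance(k, str) else k
                cp[(int(cond), direction)] = float(v)
            g["correction_probability"] = cp
        for key in ("reach_latency_ms", "reach_duration_ms", "submovement_duration_ms"):
            if key in g:
                g[key] = tuple(g[key])
        groups[name] = GroupParams(**g)
    return groups


def generator_config_from_dict(d: Mapping) -> GeneratorConfig:
    d = dict(d)
    if "groups" in d:
        d["groups"] = _groups_from_dict(d["groups"])
    if "participants" in d:
        d["participants"] = [tuple(p) for p in d["participants"]]
    if "perturbation_times" in d:
        d["perturbation_times"] = tuple(int(t) for t in d["perturbation_times"])
    if "trial_mix" in d:
        d["trial_mix"] = tuple(d["trial_mix"])
    if "foreperiod_ms" in d:
        d["foreperiod_ms"] = tuple(d["foreperiod_ms"])
    cfg = GeneratorConfig(**d)
    cfg.validate()
    return cfg


def pipeline_config_from_dict(d: Mapping) -> PipelineConfig:
    d = dict(d)
    if "generator" in d:
        d["generator"] = generator_config_from_dict(d["generator"])
    if "detector" in d:
        d["detector"] = DetectorConfig(**d["detector"])
    if "mad_variables" in d:
        d["mad_variables"] = tuple(d["mad_variables"])
    return PipelineConfig(**d)


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {
            ("_".join(str(x) for x in k) if isinstance(k, tuple) else str(k)): _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def config_to_dict(cfg) -> dict:
    return _jsonable(asdict(cfg))


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return pipeline_config_from_dict(data)


def dump_config(cfg, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)
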