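"""Model/Results interface tying the pipeline stages together.

:class:`DoubleStepAnalysis` is constructed from a :class:`~doublestep.trajectory.Session`
(plus analysis settings) and ``fit()`` runs the full pipeline — error-trial
screening, zero-phase low-pass filtering, kinematic landmarking, MAD
outlier rejection, envelope construction and correction detection —
returning a :class:`DoubleStepResults` that carries the per-trial tables,
the cleaning report, cell summaries and a printable ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import correction as corr
from . import summaries as summ
from .config import DetectorConfig, PipelineConfig, deg_to_cm
from .kinematics import absolute_x_accuracy, kinematic_profile
from .trajectory import (CleaningReport, Session, filter_trial,
                         mad_screen_trials, screen_error_trials)

DV_COLUMNS = [
    "reach_latency_ms", "reach_duration_ms", "peak_velocity_cm_s",
    "acceleration_time_ms", "deceleration_time_ms", "absolute_x_accuracy_deg",
]


class DoubleStepAnalysis:
    """Envelope-based analysis of a double-step pointing session.

    Parameters
    ----------
    session : Session
        Trials to analyse (typically loaded via :func:`doublestep.io.read_session`
        or produced by :func:`doublestep.simulate.generate_session`).
    detector : DetectorConfig, optional
        Envelope/detector settings (k·SD, minimum visuomotor delay, sustain
        run length, grouping, minimum support).
    filter_cutoff, filter_order :
        Two-way Butterworth low-pass applied to each coordinate.
    mad_threshold, mad_variables :
        Robust outlier screening of per-trial measures, applied per
        participant × condition × direction cell.
    viewing_distance_cm, perturbation_eccentricity_deg, speed_mode :
        Geometry and speed conventions for the dependent variables.
    """

    def __init__(self, session: Session, detector: DetectorConfig | None = None,
                 filter_cutoff: float = 20.0, filter_order: int = 4,
                 mad_threshold: float = 3.0,
                 mad_variables: tuple[str, ...] = ("reach_latency_ms",),
                 viewing_distance_cm: float = 40.0,
                 perturbation_eccentricity_deg: float = 10.0,
                 speed_mode: str = "3d"):
        self.session = session
        self.detector = detector or DetectorConfig()
        self.filter_cutoff = filter_cutoff
        self.filter_order = filter_order
        self.mad_threshold = mad_threshold
        self.mad_variables = tuple(mad_variables)
        self.viewing_distance_cm = viewing_distance_cm
        self.perturbation_eccentricity_deg = perturbation_eccentricity_deg
        self.speed_mode = speed_mode

    @classmethod
    def from_config(cls, session: Session, config: PipelineConfig) -> "DoubleStepAnalysis":
        return cls(
            session,
            detector=config.detector,
            filter_cutoff=config.filter_cutoff,
            filter_order=config.filter_order,
            mad_threshold=config.mad_threshold,
            mad_variables=config.mad_variables,
            viewing_distance_cm=config.generator.viewing_distance,
            perturbation_eccentricity_deg=config.generator.perturbation_eccentricity,
            speed_mode=config.speed_mode,
        )

    # ------------------------------------------------------------------
    def _final_target_x(self, trial) -> float:
        if not trial.perturbed:
            return 0.0
        sign = 1.0 if trial.direction == "right" else -1.0
        return sign * deg_to_cm(self.perturbation_eccentricity_deg, self.viewing_distance_cm)

    def fit(self) -> "DoubleStepResults":
        fs = self.session.sampling_rate

        # stage 1: rule-based screening
        screened, report = screen_error_trials(self.session)

        # stage 2: zero-phase filtering (trials too short to filter are excluded)
        filtered = []
        for trial in screened:
            try:
                filtered.append(filter_trial(trial, fs, self.filter_cutoff, self.filter_order))
            except ValueError:
                report.removed_screening.append((trial.key, "too short to filter"))
        screened = Session(filtered, fs, dict(screened.metadata))

        # stage 3: kinematic dependent variables
        rows = []
        for trial in screened:
            prof = kinematic_profile(trial, self.speed_mode)
            rows.append({
                "participant": trial.participant, "group": trial.group,
                "block": trial.block, "trial": trial.trial,
                "condition_ms": math.nan if trial.condition_ms is None else trial.condition_ms,
                "direction": trial.direction,
                "reach_latency_ms": prof.reach_latency_ms,
                "reach_duration_ms": prof.reach_duration_ms,
                "peak_velocity_cm_s": prof.peak_velocity_cm_s,
                "acceleration_time_ms": prof.acceleration_time_ms,
                "deceleration_time_ms": prof.deceleration_time_ms,
                "absolute_x_accuracy_deg": absolute_x_accuracy(
                    trial, self._final_target_x(trial), self.viewing_distance_cm),
                "degenerate_profile": prof.degenerate,
            })
        trial_table = pd.DataFrame(rows)

        # stage 4: MAD outlier rejection on per-trial measures
        if len(trial_table):
            mask, reasons = mad_screen_trials(trial_table, self.mad_variables,
                                              self.mad_threshold)
            report.removed_mad.extend(reasons)
            trial_table = trial_table[~mask].reset_index(drop=True)
            removed = {k for k, _ in reasons}
            screened = screened.select(lambda t: t.key not in removed)

        # stage 5: envelopes from retained non-perturbed trials
        envelopes = corr.build_envelopes(
            screened, k=self.detector.k_sd, min_support=self.detector.min_support,
            grouping=self.detector.grouping)

        # stage 6: correction detection + path offsets on perturbed trials
        crows = []
        for trial in screened:
            if not trial.perturbed:
                continue
            key = corr.envelope_key(trial, self.detector.grouping)
            if key not in envelopes:
                raise ValueError(
                    f"no envelope for grouping unit {key}: session lacks "
                    f"non-perturbed trials there (build_envelope precondition)")
            res = corr.CorrectionResult(key=trial.key)
            try:
                corr.detect_correction(trial, envelopes[key],
                                       min_delay_ms=self.detector.min_delay_ms,
                                       sustain=self.detector.sustain, result=res)
            except ValueError as exc:
                res.flags.append(str(exc))
            L, A, B, idx = corr.trial_path_linearity(trial)
            res.L, res.A_cm, res.B_cm, res.mpo_index = L, A, B, idx
            if idx >= 0:
                res.mpo_latency_ms = corr.mpo_latency(trial, idx)
            crows.append({
                "participant": trial.participant, "group": trial.group,
                "block": trial.block, "trial": trial.trial,
                "condition_ms": trial.condition_ms, "direction": trial.direction,
                "detected": res.detected,
                "correction_latency_ms": res.correction_latency_ms,
                "pre_deviated": res.pre_deviated,
                "opposite_crossing": res.opposite_crossing,
                "L": res.L, "A_cm": res.A_cm, "B_cm": res.B_cm,
                "mpo_latency_ms": res.mpo_latency_ms,
                "flags": ";".join(res.flags),
            })
        corrections = pd.DataFrame(crows)

        return DoubleStepResults(
            model=self, session=screened, trial_table=trial_table,
            corrections=corrections, cleaning=report, envelopes=envelopes)


@dataclass
class DoubleStepResults:
    """Fitted results: per-trial tables, cleaning report, envelopes, summaries."""

    model: DoubleStepAnalysis
    session: Session
    trial_table: pd.DataFrame
    corrections: pd.DataFrame
    cleaning: CleaningReport
    envelopes: dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    def correction_frequency(self) -> pd.DataFrame:
        """Percent of perturbed trials with a detected correction, per cell."""
        if self.corrections.empty:
            return pd.DataFrame()
        return corr.correction_frequency(self.corrections)

    def summary_table(self, variables: list[str] | None = None,
                      two_stage: bool = True) -> pd.DataFrame:
        return summ.condition_summary(self.trial_table, variables or DV_COLUMNS,
                                      two_stage=two_stage)

    def participant_table(self, variables: list[str] | None = None) -> pd.DataFrame:
        """Participant-level means, ready for an external stats environment."""
        return summ.participant_means(self.trial_table, variables or DV_COLUMNS)

    def group_percent_difference(self, variable: str) -> int:
        """Percent difference between the two group means of one measure."""
        means = self.trial_table.groupby("group")[variable].mean()
        if len(means) != 2:
            raise ValueError("percent difference needs exactly two groups")
        return summ.percent_difference(float(means.iloc[0]), float(means.iloc[1]))

    def save(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fmt = "%.9f"
        self.trial_table.to_csv(outdir / "trials.csv", index=False, float_format=fmt)
        self.corrections.to_csv(outdir / "corrections.csv", index=False, float_format=fmt)
        self.cleaning.to_frame().to_csv(outdir / "cleaning.csv", index=False)
        freq = self.correction_frequency()
        if len(freq):
            freq.to_csv(outdir / "correction_frequency.csv", float_format=fmt)
        self.summary_table().to_csv(outdir / "summary.csv", index=False, float_format=fmt)
        self.participant_table().to_csv(outdir / "participant_means.csv",
                                        index=False, float_format=fmt)

    # ------------------------------------------------------------------
    def summary(self) -> str:
        """Printable overview of cleaning, detection and the main measures."""
        lines = ["Double-step reach analysis", "=" * 62]
        rep = self.cleaning
        lines.append(
            f"Trials: {rep.n_input} in, {len(rep.removed_screening)} removed at "
            f"screening, {len(rep.removed_mad)} MAD outliers, {rep.n_retained} retained "
            f"({100 * rep.fraction_removed:.1f}% removed)")
        if len(self.corrections):
            det = self.corrections["detected"]
            lat = self.corrections.loc[det, "correction_latency_ms"]
            lines.append(
                f"Perturbed trials: {len(det)}; corrections detected on "
                f"{100 * det.mean():.1f}%"
                + (f"; median latency {lat.median():.1f} ms" if det.any() else ""))
            freq = self.correction_frequency()
            lines.append("")
            lines.append("Correction frequency (% of perturbed trials):")
            lines.append(freq.round(1).to_string())
        lines.append("")
        lines.append("Cell means (participant-mean aggregation):")
        tbl = self.summary_table()
        show = ["group", "condition_ms", "direction", "n_trials"] + \
               [c for c in tbl.columns if c.endswith("_mean")]
        lines.append(tbl[show].round(2).to_string(index=False))
        return "\n".join(lines)
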