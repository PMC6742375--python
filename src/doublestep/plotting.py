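"""Diagnostic trajectory figures (optional; matplotlib)."""

from __future__ import annotations

import numpy as np

from .correction import Envelope, CorrectionResult
from .trajectory import Trial


def plot_envelope_detection(trial: Trial, envelope: Envelope,
                            result: CorrectionResult | None = None, ax=None):
    """Horizontal trace of one perturbed trial against the ±k·SD envelope."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sel = trial.t_s >= trial.reach_onset_s - 1e-9
    t_ms = (trial.t_s[sel] - trial.reach_onset_s) * 1000.0
    x = trial.x_cm[sel]
    lo, hi = envelope.bounds(len(x))
    mean, _ = envelope.resampled(len(x))
    ax.fill_between(t_ms, lo, hi, alpha=0.25, color="0.5", label="±k·SD envelope")
    ax.plot(t_ms, mean, "k-", lw=1, label="non-perturbed mean")
    ax.plot(t_ms, x, "r--", lw=1, label="perturbed trial")
    if trial.perturbation_s is not None:
        pert_ms = (trial.perturbation_s - trial.reach_onset_s) * 1000.0
        ax.axvline(pert_ms, color="b", ls=":", lw=1, label="perturbation")
        if result is not None and result.detected:
            ax.axvline(pert_ms + result.correction_latency_ms, color="g", ls="-.",
                       lw=1, label="detected correction")
    ax.set_xlabel("time from reach onset (ms)")
    ax.set_ylabel("horizontal position (cm)")
    ax.legend(fontsize=8)
    return ax
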