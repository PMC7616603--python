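"""Epoch-level preprocessing: baseline correction and noisy-trial rejection.

Raw-EEG steps (band-pass filtering, down-sampling, ICA) are assumed done
upstream; this module operates on the epoched container only.  Trial
rejection is a deterministic two-rule heuristic standing in for manual
inspection: a trial is flagged when its worst channel peak-to-peak
amplitude exceeds a µV threshold, or when its log-variance is an outlier
across trials.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .datatypes import EpochSet
from .exceptions import ValidationError

logger = logging.getLogger("contextrsa")

#: Default trial-rejection thresholds.
DEFAULT_PTP_THRESHOLD_UV = 200.0
DEFAULT_ZVAR_THRESHOLD = 4.0


def baseline_correct(
    epochs: EpochSet, window_start_ms: float = -200.0, window_end_ms: float = 0.0
) -> EpochSet:
    """Subtract the per-trial, per-channel mean over a baseline window.

    The window is a closed interval evaluated on the time grid.  The
    operation is idempotent: the corrected baseline window has mean 0, so
    applying it again changes nothing.

    Raises
    ------
    ValidationError
        If the window is empty or lies outside the epoch.
    """
    if window_end_ms < window_start_ms:
        raise ValidationError(
            f"baseline window ({window_start_ms}, {window_end_ms}) is empty (end < start)"
        )
    if window_start_ms < epochs.times[0] - 1e-9 or window_end_ms > epochs.times[-1] + 1e-9:
        raise ValidationError(
            f"baseline window [{window_start_ms}, {window_end_ms}] ms outside epoch "
            f"range [{epochs.times[0]:g}, {epochs.times[-1]:g}] ms"
        )
    sel = (epochs.times >= window_start_ms) & (epochs.times <= window_end_ms)
    if not sel.any():
        raise ValidationError(
            f"baseline window [{window_start_ms}, {window_end_ms}] ms contains no grid points"
        )
    mean = epochs.data[:, :, sel].mean(axis=2, keepdims=True)
    return dataclasses.replace(epochs, data=epochs.data - mean)


def reject_noisy_trials(
    epochs: EpochSet,
    ptp_threshold_uv: float = DEFAULT_PTP_THRESHOLD_UV,
    zvar_threshold: float = DEFAULT_ZVAR_THRESHOLD,
) -> EpochSet:
    """Flag noisy trials (keep=False) without altering amplitudes.

    Rule 1 — amplitude: the maximum over channels of the trial's
    peak-to-peak amplitude exceeds ``ptp_threshold_uv``.
    Rule 2 — variance: the z-score (across trials) of the trial's
    log-variance (pooled over channels and timepoints) exceeds
    ``zvar_threshold``.

    Raises
    ------
    ValidationError
        If a threshold is non-positive or every trial would be rejected.
    """
    if ptp_threshold_uv <= 0 or zvar_threshold <= 0:
        raise ValidationError("rejection thresholds must be positive")
    ptp = np.ptp(epochs.data, axis=2).max(axis=1)  # worst channel per trial
    var = epochs.data.reshape(epochs.n_trials, -1).var(axis=1)
    with np.errstate(divide="ignore"):
        logv = np.log(var)
    sd = logv.std(ddof=1) if epochs.n_trials > 1 else 0.0
    if sd > 0:
        z = (logv - logv.mean()) / sd
    else:
        z = np.zeros_like(logv)
    bad = (ptp > ptp_threshold_uv) | (z > zvar_threshold)
    if bad.all():
        raise ValidationError(
            f"all {epochs.n_trials} trials rejected (ptp > {ptp_threshold_uv} µV or "
            f"log-variance z > {zvar_threshold}); analysis impossible"
        )
    n_bad = int(bad.sum())
    if n_bad:
        logger.info(
            "subject %s: rejecting %d/%d trials (%.1f%%)",
            epochs.subject_id, n_bad, epochs.n_trials, 100 * n_bad / epochs.n_trials,
        )
    trials = epochs.trials.copy()
    trials.loc[bad, "keep"] = False
    return dataclasses.replace(epochs, trials=trials)
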