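"""Per-timepoint neural RDMs from multichannel epochs.

At each timepoint every trial contributes a pattern: its vector of channel
amplitudes.  Dissimilarity between two trials is the correlation distance
1 − Pearson r between their patterns, giving one trials × trials RDM per
timepoint.  Patterns are single-timepoint channel vectors by default; an
optional sliding-window average over neighbouring timepoints is available
for noise robustness.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import correlation as _scipy_correlation

from .datatypes import EpochSet, NeuralRDMSeries
from .exceptions import ValidationError, ZeroVarianceError

_CONST_TOL = 1e-12


def correlation_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Correlation distance 1 − Pearson(p, q), in [0, 2].

    Raises
    ------
    ZeroVarianceError
        If either pattern is constant (Pearson undefined) or shorter than 3.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.size < 3 or q.size < 3:
        raise ValidationError("correlation distance needs patterns of length >= 3")
    if np.ptp(p) <= _CONST_TOL or np.ptp(q) <= _CONST_TOL:
        raise ZeroVarianceError("correlation distance undefined for a constant pattern")
    return float(np.clip(_scipy_correlation(p, q), 0.0, 2.0))


def neural_rdm_series(epochs: EpochSet, window_samples: int = 1) -> NeuralRDMSeries:
    """Correlation-distance RDM at every timepoint, over kept trials.

    Parameters
    ----------
    epochs
        Epoch set; only kept trials enter the RDMs.  All channels are used.
    window_samples
        Odd number of timepoints to average (boxcar, centred) before
        computing patterns; 1 (default) means single-timepoint patterns.

    Returns
    -------
    NeuralRDMSeries
        Labelled by trial_id, one RDM per timepoint.

    Raises
    ------
    ZeroVarianceError
        Naming the trial and timepoint of any constant channel pattern.
    """
    kept = epochs.kept()
    if kept.n_trials < 2:
        raise ValidationError(f"neural RDMs need >= 2 kept trials; got {kept.n_trials}")
    if kept.n_channels < 3:
        raise ValidationError(f"neural RDMs need >= 3 channels; got {kept.n_channels}")
    data = kept.data
    if window_samples != 1:
        if window_samples < 1 or window_samples % 2 == 0:
            raise ValidationError("window_samples must be a positive odd integer")
        kernel = np.ones(window_samples) / window_samples
        pad = window_samples // 2
        padded = np.pad(data, ((0, 0), (0, 0), (pad, pad)), mode="edge")
        data = np.apply_along_axis(lambda x: np.convolve(x, kernel, mode="valid"), 2, padded)

    centred = data - data.mean(axis=1, keepdims=True)  # remove channel mean per trial/time
    norms = np.sqrt(np.einsum("ict,ict->it", centred, centred))  # (trial, time)
    flat_sd = norms <= _CONST_TOL * max(1.0, np.abs(data).max())
    if flat_sd.any():
        ti, tp = np.argwhere(flat_sd)[0]
        raise ZeroVarianceError(
            f"constant channel pattern for trial_id "
            f"{kept.trials['trial_id'].iloc[int(ti)]} at timepoint index {int(tp)} "
            f"({kept.times[int(tp)]:g} ms); correlation distance undefined"
        )
    unit = centred / norms[:, None, :]
    # corr(i, j, t) = sum_c unit[i, c, t] * unit[j, c, t]; batch over time
    u = np.ascontiguousarray(unit.transpose(2, 0, 1))  # (time, trial, channel)
    corr = u @ u.transpose(0, 2, 1)  # (time, trial, trial)
    dissim = 0.5 * (corr + corr.transpose(0, 2, 1))  # guard exact symmetry
    np.subtract(1.0, dissim, out=dissim)
    np.maximum(dissim, 0.0, out=dissim)
    np.minimum(dissim, 2.0, out=dissim)
    idx = np.arange(kept.n_trials)
    dissim[:, idx, idx] = 0.0
    return NeuralRDMSeries(kept.times, list(kept.trials["trial_id"]), dissim, "correlation")


def subset_rdm_series(series: NeuralRDMSeries, labels) -> NeuralRDMSeries:
    """Restrict a neural RDM series to the given trial_ids, in order."""
    return series.subset(labels)
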