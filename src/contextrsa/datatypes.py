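"""Domain containers for epoched EEG, trial metadata, feature norms and RDMs.

The central objects are :class:`EpochSet` (one participant's trials ×
channels × timepoints array plus a trial table), :class:`FeatureNorms`
(a non-negative concept × feature property-norm matrix), :class:`RDM`
(a labelled symmetric dissimilarity matrix) and :class:`NeuralRDMSeries`
(one RDM per timepoint).  All of them validate their invariants on
construction so that downstream analysis code can assume well-formed
inputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError, ZeroVarianceError

#: The two scene-object conditions, in canonical order.
CONDITIONS = ("congruent", "incongruent")

#: Required columns of a trial table, in canonical order.
TRIAL_COLUMNS = ("trial_id", "scene_id", "object_label", "condition", "keep")

#: Recognised dissimilarity metrics for an RDM.
RDM_METRICS = ("euclidean", "cosine", "correlation")

_TIME_SPACING_TOL = 1e-9


def validate_trial_table(trials: pd.DataFrame, *, require_unique_scenes: bool = False) -> pd.DataFrame:
    """Validate (and lightly normalise) a per-trial metadata table.

    Parameters
    ----------
    trials
        DataFrame with columns ``trial_id`` (int), ``scene_id`` (str),
        ``object_label`` (str), ``condition`` (``congruent`` or
        ``incongruent``) and ``keep`` (bool).
    require_unique_scenes
        If True additionally enforce the counterbalanced-design invariant
        that every scene appears exactly once.

    Returns
    -------
    DataFrame
        A copy with canonical column order and dtypes.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValidationError(f"trial table is missing columns {missing}")
    t = trials.loc[:, list(TRIAL_COLUMNS)].copy()
    t["trial_id"] = t["trial_id"].astype(np.int64)
    t["keep"] = t["keep"].astype(bool)
    for col in ("scene_id", "object_label", "condition"):
        t[col] = t[col].astype(str)
    if t["trial_id"].duplicated().any():
        dup = t.loc[t["trial_id"].duplicated(), "trial_id"].iloc[0]
        raise ValidationError(f"duplicate trial_id {dup} in trial table")
    bad = ~t["condition"].isin(CONDITIONS)
    if (bad & t["keep"]).any():
        row = t.index[bad & t["keep"]][0]
        raise ValidationError(
            f"unknown condition {t.loc[row, 'condition']!r} for kept trial_id "
            f"{t.loc[row, 'trial_id']} (expected one of {CONDITIONS})"
        )
    if require_unique_scenes and t["scene_id"].duplicated().any():
        dup = t.loc[t["scene_id"].duplicated(), "scene_id"].iloc[0]
        raise ValidationError(f"scene_id {dup!r} appears more than once in a design-conforming table")
    return t.reset_index(drop=True)


@dataclass
class EpochSet:
    """One participant's epoched EEG: trials × channels × timepoints, in µV.

    Attributes
    ----------
    subject_id : str
    data : ndarray, shape (n_trials, n_channels, n_times)
        Amplitudes in µV, float64, finite.
    times : ndarray, shape (n_times,)
        Time axis in milliseconds, strictly increasing, uniformly spaced,
        consistent with ``sfreq``.
    channel_names : list of str
    sfreq : float
        Sampling frequency in Hz.
    trials : DataFrame
        Per-trial metadata, one row per trial (first data axis).
    """

    subject_id: str
    data: np.ndarray
    times: np.ndarray
    channel_names: list[str]
    sfreq: float
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.channel_names = [str(c) for c in self.channel_names]
        self.trials = validate_trial_table(self.trials)
        if self.data.ndim != 3:
            raise ValidationError(f"epoch data must be 3-D (trial, channel, time); got shape {self.data.shape}")
        n_trials, n_channels, n_times = self.data.shape
        if n_trials == 0:
            raise ValidationError("EpochSet with zero trials is invalid")
        if len(self.trials) != n_trials:
            raise ValidationError(
                f"trial table has {len(self.trials)} rows but data has {n_trials} trials"
            )
        if len(self.channel_names) != n_channels:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for {n_channels} data channels"
            )
        if self.times.shape != (n_times,):
            raise ValidationError(
                f"times has length {self.times.size} but data has {n_times} timepoints"
            )
        if n_times >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValidationError("times must be strictly increasing")
            if np.ptp(steps) > _TIME_SPACING_TOL:
                raise ValidationError("times must be uniformly spaced (spacing varies by more than 1e-9 ms)")
            expected = 1000.0 / float(self.sfreq)
            if abs(steps[0] - expected) > _TIME_SPACING_TOL:
                raise ValidationError(
                    f"time spacing {steps[0]} ms inconsistent with sfreq {self.sfreq} Hz "
                    f"(expected {expected} ms)"
                )
        if not np.isfinite(self.data).all():
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise ValidationError(
                f"non-finite amplitude at (trial={bad[0]}, channel={bad[1]}, timepoint={bad[2]})"
            )

    # -- convenience -------------------------------------------------------

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def kept_mask(self) -> np.ndarray:
        return self.trials["keep"].to_numpy()

    def kept(self) -> "EpochSet":
        """Return a view-copy restricted to kept trials."""
        mask = self.kept_mask
        if mask.all():
            return self
        return dataclasses.replace(
            self,
            data=self.data[mask],
            trials=self.trials.loc[mask].reset_index(drop=True),
        )

    def crop(self, tmin: float, tmax: float) -> "EpochSet":
        """Restrict the time axis to the closed interval [tmin, tmax] ms."""
        sel = (self.times >= tmin) & (self.times <= tmax)
        if not sel.any():
            raise ValidationError(f"crop window [{tmin}, {tmax}] ms contains no timepoints")
        return dataclasses.replace(self, data=self.data[:, :, sel], times=self.times[sel])

    def copy(self) -> "EpochSet":
        return dataclasses.replace(
            self,
            data=self.data.copy(),
            times=self.times.copy(),
            channel_names=list(self.channel_names),
            trials=self.trials.copy(),
        )


@dataclass
class FeatureNorms:
    """Concept × feature property-norm matrix (non-negative).

    Concept names are case-normalised (lower-cased, stripped) and must be
    unique after normalisation; a concept with no positive feature value is
    invalid.
    """

    concepts: list[str]
    features: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.concepts = [str(c).strip().lower() for c in self.concepts]
        self.features = [str(f) for f in self.features]
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.concepts), len(self.features)):
            raise ValidationError(
                f"norms matrix shape {self.values.shape} does not match "
                f"{len(self.concepts)} concepts × {len(self.features)} features"
            )
        if len(set(self.concepts)) != len(self.concepts):
            seen: set[str] = set()
            dup = next(c for c in self.concepts if c in seen or seen.add(c))
            raise ValidationError(f"duplicate concept {dup!r} after case normalisation")
        if np.any(self.values < 0):
            c, f = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative norm value for concept {self.concepts[c]!r}, feature {self.features[f]!r}"
            )
        row_zero = ~(self.values > 0).any(axis=1)
        if row_zero.any():
            c = int(np.flatnonzero(row_zero)[0])
            raise ValidationError(f"concept {self.concepts[c]!r} has no positive feature (all-zero row)")
        self._index = {c: i for i, c in enumerate(self.concepts)}

    @property
    def n_concepts(self) -> int:
        return len(self.concepts)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def __contains__(self, concept: str) -> bool:
        return str(concept).strip().lower() in self._index

    def vector(self, concept: str) -> np.ndarray:
        """Feature vector for a concept (case-insensitive lookup)."""
        key = str(concept).strip().lower()
        if key not in self._index:
            raise KeyError(f"concept {concept!r} not in norms")
        return self.values[self._index[key]]


@dataclass
class RDM:
    """Labelled symmetric dissimilarity matrix with a zero diagonal.

    ``metric`` tags how the dissimilarities were computed: ``euclidean``
    (here: Euclidean distance on binary condition codes, entries in {0, 1}),
    ``cosine`` (1 − cosine similarity, in [0, 1] for non-negative vectors)
    or ``correlation`` (1 − Pearson r, in [0, 2]).
    """

    labels: list
    matrix: np.ndarray
    metric: str

    _SYM_TOL = 1e-12

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValidationError(f"RDM matrix shape {self.matrix.shape} does not match {n} labels")
        if n < 2:
            raise ValidationError("an RDM needs at least 2 items")
        if self.metric not in RDM_METRICS:
            raise ValidationError(f"unknown RDM metric {self.metric!r}; expected one of {RDM_METRICS}")
        if np.abs(self.matrix - self.matrix.T).max() > self._SYM_TOL:
            raise ValidationError("RDM matrix is not symmetric to within 1e-12")
        if np.any(np.diag(self.matrix) != 0):
            raise ValidationError("RDM diagonal must be exactly 0")
        off = self.matrix[np.triu_indices(n, k=1)]
        if self.metric == "euclidean" and not np.isin(off, (0.0, 1.0)).all():
            raise ValidationError("euclidean-on-binary RDM entries must be 0 or 1")
        hi = 1.0 if self.metric == "cosine" else 2.0
        if self.metric in ("cosine", "correlation") and (off.min() < -self._SYM_TOL or off.max() > hi + 1e-9):
            raise ValidationError(f"{self.metric} RDM entries out of range [0, {hi}]")

    @property
    def n_items(self) -> int:
        return len(self.labels)

    def triangle(self) -> np.ndarray:
        """Strictly-lower-triangle vectorisation (diagonal excluded)."""
        i, j = np.tril_indices(self.n_items, k=-1)
        return self.matrix[i, j]

    def subset(self, labels: Sequence) -> "RDM":
        """Restrict to the given labels, in the given order."""
        idx = _label_indices(self.labels, labels)
        return RDM(list(labels), self.matrix[np.ix_(idx, idx)], self.metric)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def _label_indices(have: Sequence, want: Sequence) -> np.ndarray:
    pos = {lab: i for i, lab in enumerate(have)}
    try:
        return np.array([pos[lab] for lab in want], dtype=np.intp)
    except KeyError as exc:
        raise ValidationError(f"unknown label {exc.args[0]!r}") from None


@dataclass
class NeuralRDMSeries:
    """A stack of correlation-distance RDMs, one per timepoint.

    Stored internally as a (n_times, n_items, n_items) array with a shared
    label list; :meth:`rdm_at` materialises the RDM of a single timepoint.
    """

    times: np.ndarray
    labels: list
    dissimilarities: np.ndarray
    metric: str = "correlation"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.labels = list(self.labels)
        self.dissimilarities = np.asarray(self.dissimilarities, dtype=np.float64)
        n_t, n = self.times.size, len(self.labels)
        if self.dissimilarities.shape != (n_t, n, n):
            raise ValidationError(
                f"dissimilarity stack shape {self.dissimilarities.shape} does not match "
                f"{n_t} timepoints × {n} items"
            )

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_items(self) -> int:
        return len(self.labels)

    def rdm_at(self, index: int) -> RDM:
        return RDM(self.labels, self.dissimilarities[index], self.metric)

    def __iter__(self) -> Iterator[RDM]:
        for i in range(len(self)):
            yield self.rdm_at(i)

    @property
    def rdms(self) -> list[RDM]:
        return list(self)

    def subset(self, labels: Sequence) -> "NeuralRDMSeries":
        """Restrict every timepoint's RDM to the given labels, in order."""
        if len(labels) < 2:
            raise ValidationError("an RDM needs at least 2 items; cannot subset below 2 labels")
        idx = _label_indices(self.labels, labels)
        return NeuralRDMSeries(
            self.times, list(labels), self.dissimilarities[:, idx[:, None], idx[None, :]], self.metric
        )

    def triangles(self) -> np.ndarray:
        """(n_times, n_pairs) matrix of strictly-lower-triangle vectorisations."""
        i, j = np.tril_indices(self.n_items, k=-1)
        return self.dissimilarities[:, i, j]


@dataclass
class RSATimeSeries:
    """Per-timepoint Spearman model fit for one participant."""

    subject_id: str
    times: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.rho = np.asarray(self.rho, dtype=np.float64)
        if self.times.shape != self.rho.shape:
            raise ValidationError("times and rho must have matching lengths")
        finite = self.rho[np.isfinite(self.rho)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValidationError("Spearman rho out of [-1, 1]")


@dataclass
class ClusterResult:
    """A contiguous suprathreshold run of timepoints with its signed mass.

    ``mass`` is the sum of t-values across the run; ``p_value`` is assigned
    by the permutation test (None until then).
    """

    start_time: float
    end_time: float
    start_index: int
    end_index: int  # inclusive
    mass: float
    p_value: float | None = None

    @property
    def timepoint_indices(self) -> np.ndarray:
        return np.arange(self.start_index, self.end_index + 1)

    @property
    def sign(self) -> int:
        return 1 if self.mass >= 0 else -1

    def to_dict(self) -> dict:
        return {
            "start_ms": float(self.start_time),
            "end_ms": float(self.end_time),
            "start_index": int(self.start_index),
            "end_index": int(self.end_index),
            "mass": float(self.mass),
            "p_value": None if self.p_value is None else float(self.p_value),
        }


@dataclass
class GroupRSAResult:
    """Group-level RSA inference: per-subject fits, t-values and clusters.

    Returned by the sign-flip and paired cluster-mass permutation tests.
    """

    times: np.ndarray
    rho: np.ndarray  # (n_subjects, n_times)
    subject_ids: list[str]
    tvalues: np.ndarray
    clusters: list[ClusterResult]
    n_permutations: int
    alpha_cluster_forming: float
    cluster_forming_threshold: float
    seed: int
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.rho = np.asarray(self.rho, dtype=np.float64)
        for c in self.clusters:
            if not (self.times[0] <= c.start_time <= c.end_time <= self.times[-1]):
                raise ValidationError("cluster span lies outside the time axis")
            if c.p_value is not None and not (
                1.0 / (self.n_permutations + 1) - 1e-12 <= c.p_value <= 1.0
            ):
                raise ValidationError("cluster p-value outside [1/(n_perm+1), 1]")

    @property
    def n_subjects(self) -> int:
        return self.rho.shape[0]

    @property
    def mean_rho(self) -> np.ndarray:
        return self.rho.mean(axis=0)

    def significant_clusters(self, alpha: float = 0.05) -> list[ClusterResult]:
        return [c for c in self.clusters if c.p_value is not None and c.p_value <= alpha]

    def summary(self) -> str:
        """Plain-text summary table in the style of a model-fit report."""
        lines = [
            f"Group RSA result{': ' + self.label if self.label else ''}",
            f"  subjects: {self.n_subjects}   timepoints: {self.times.size} "
            f"({self.times[0]:g}..{self.times[-1]:g} ms)",
            f"  cluster-forming alpha: {self.alpha_cluster_forming}  "
            f"(|t| > {self.cluster_forming_threshold:.4f})",
            f"  permutations: {self.n_permutations}   seed: {self.seed}",
            f"  peak mean rho: {self.mean_rho.max():.4f} at "
            f"{self.times[int(np.argmax(self.mean_rho))]:g} ms",
        ]
        if self.clusters:
            lines.append("  clusters (start ms, end ms, mass, p):")
            for c in self.clusters:
                p = "   n/a" if c.p_value is None else f"{c.p_value:.4f}"
                lines.append(
                    f"    {c.start_time:8.1f} {c.end_time:8.1f} {c.mass:10.2f}   p = {p}"
                )
        else:
            lines.append("  clusters: none")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_subjects": self.n_subjects,
            "n_permutations": int(self.n_permutations),
            "alpha_cluster_forming": float(self.alpha_cluster_forming),
            "cluster_forming_threshold": float(self.cluster_forming_threshold),
            "seed": int(self.seed),
            "clusters": [c.to_dict() for c in self.clusters],
        }

    def plot(self, ax=None):
        """Line plot of the group-mean fit with significant-cluster bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.mean_rho
        se = self.rho.std(axis=0, ddof=1) / np.sqrt(self.n_subjects)
        ax.plot(self.times, m, label=self.label or "model fit")
        ax.fill_between(self.times, m - se, m + se, alpha=0.3)
        y0 = m.min() - 2 * se.max()
        for c in self.significant_clusters():
            ax.hlines(y0, c.start_time, c.end_time, lw=3)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("Spearman rho")
        return ax
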