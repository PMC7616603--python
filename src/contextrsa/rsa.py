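"""Model objects tying the pipeline together, statsmodels-style.

:class:`CongruencyRSA` and :class:`SemanticRSA` are built from a cohort of
:class:`~contextrsa.datatypes.EpochSet` objects; their ``fit()`` runs the
per-subject RSA and the group-level cluster-mass permutation inference and
returns result objects carrying per-subject fits, t-values, clusters with
permutation p-values, and a ``summary()`` table.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .datatypes import CONDITIONS, EpochSet, FeatureNorms, GroupRSAResult, RSATimeSeries
from .exceptions import ValidationError
from .inference import (
    paired_cluster_test,
    rsa_timeseries,
    signflip_cluster_test,
    timecourse_correlation,
)
from .modelrdm import build_congruency_rdm, build_semantic_rdm, match_concepts
from .neural import neural_rdm_series
from .preprocess import (
    DEFAULT_PTP_THRESHOLD_UV,
    DEFAULT_ZVAR_THRESHOLD,
    baseline_correct,
    reject_noisy_trials,
)

logger = logging.getLogger("contextrsa")


def _preprocess(
    epochs: EpochSet,
    baseline_window: tuple[float, float] | None,
    reject: bool,
    ptp_threshold_uv: float,
    zvar_threshold: float,
) -> EpochSet:
    # rejection first, baseline second
    if reject:
        epochs = reject_noisy_trials(epochs, ptp_threshold_uv, zvar_threshold)
    if baseline_window is not None:
        epochs = baseline_correct(epochs, *baseline_window)
    return epochs


def _common_times(subjects: Sequence[EpochSet]) -> np.ndarray:
    times = subjects[0].times
    for s in subjects[1:]:
        if s.times.shape != times.shape or not np.allclose(s.times, times, atol=1e-9):
            raise ValidationError(f"subject {s.subject_id} has a different time axis")
    return times


class CongruencyRSA:
    """Congruency-model RSA for a cohort of participants.

    Per participant: noisy-trial rejection, baseline correction,
    per-timepoint correlation-distance neural RDMs over all kept trials,
    a participant-specific binary congruency model RDM, and the Spearman
    fit between the two at every timepoint.  ``fit()`` then runs the
    group sign-flip cluster-mass permutation test.

    Parameters
    ----------
    subjects
        One EpochSet per participant (>= 3), sharing a time axis.
    baseline_window
        Closed ms interval for baseline correction (None to skip).
    reject, ptp_threshold_uv, zvar_threshold
        Automatic noisy-trial rejection and its thresholds.
    window_samples
        Temporal boxcar width (odd) for the neural patterns; 1 = single
        timepoint.
    """

    def __init__(
        self,
        subjects: Sequence[EpochSet],
        *,
        baseline_window: tuple[float, float] | None = (-200.0, 0.0),
        reject: bool = True,
        ptp_threshold_uv: float = DEFAULT_PTP_THRESHOLD_UV,
        zvar_threshold: float = DEFAULT_ZVAR_THRESHOLD,
        window_samples: int = 1,
    ):
        if len(subjects) < 3:
            raise ValidationError(f"group inference needs >= 3 subjects; got {len(subjects)}")
        self.subjects = [
            _preprocess(s, baseline_window, reject, ptp_threshold_uv, zvar_threshold)
            for s in subjects
        ]
        self.times = _common_times(self.subjects)
        self.window_samples = window_samples

    def subject_timeseries(self) -> list[RSATimeSeries]:
        """Per-subject congruency model fit time series."""
        out = []
        for s in self.subjects:
            series = neural_rdm_series(s, self.window_samples)
            model = build_congruency_rdm(s.trials)
            out.append(rsa_timeseries(series, model, subject_id=s.subject_id))
        return out

    def fit(
        self, alpha: float = 0.01, n_perm: int = 10000, seed: int = 0, tail: str = "two"
    ) -> GroupRSAResult:
        ts = self.subject_timeseries()
        rhos = np.stack([t.rho for t in ts])
        return signflip_cluster_test(
            rhos,
            times=self.times,
            alpha=alpha,
            n_perm=n_perm,
            seed=seed,
            subject_ids=[t.subject_id for t in ts],
            label="congruency",
            tail=tail,
        )


@dataclass
class SemanticRSAResults:
    """Per-condition semantic model fits and their paired contrast."""

    congruent: GroupRSAResult
    incongruent: GroupRSAResult
    difference: GroupRSAResult  # incongruent − congruent
    excluded_subjects: list[str] = field(default_factory=list)
    unmatched_counts: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return self.congruent.times

    def correlation_with(
        self, congruency: GroupRSAResult, window: tuple[float, float] | None = None
    ) -> tuple[float, float]:
        """Pearson correlation between the group-mean congruency fit and
        the group-mean semantic fit difference (incongruent − congruent)."""
        if congruency.times.shape != self.times.shape or not np.allclose(
            congruency.times, self.times
        ):
            raise ValidationError("congruency and semantic results have different time axes")
        x = congruency.mean_rho
        y = self.incongruent.mean_rho - self.congruent.mean_rho
        return timecourse_correlation(x, y, times=self.times, window=window)

    def summary(self) -> str:
        parts = [self.congruent.summary(), self.incongruent.summary(), self.difference.summary()]
        if self.excluded_subjects:
            parts.append(f"excluded subjects: {self.excluded_subjects}")
        return "\n\n".join(parts)


class SemanticRSA:
    """Semantic-feature RSA per condition, with the paired contrast.

    Per participant: object labels are matched to property-norm concepts
    (exact case-insensitive match, then alias table); per condition, a
    cosine-distance semantic RDM is built over the matched kept trials of
    that condition and related to the matching subset of the neural RDM
    series.  Unmatched trials are excluded from this analysis only.
    Participants with fewer than 2 usable trials in either condition are
    excluded listwise (with a warning), so the paired test sees the same
    subjects in both conditions.
    """

    def __init__(
        self,
        subjects: Sequence[EpochSet],
        norms: FeatureNorms,
        aliases: Mapping[str, str] | None = None,
        *,
        binarize: bool = False,
        baseline_window: tuple[float, float] | None = (-200.0, 0.0),
        reject: bool = True,
        ptp_threshold_uv: float = DEFAULT_PTP_THRESHOLD_UV,
        zvar_threshold: float = DEFAULT_ZVAR_THRESHOLD,
        window_samples: int = 1,
    ):
        if len(subjects) < 3:
            raise ValidationError(f"group inference needs >= 3 subjects; got {len(subjects)}")
        self.subjects = [
            _preprocess(s, baseline_window, reject, ptp_threshold_uv, zvar_threshold)
            for s in subjects
        ]
        self.times = _common_times(self.subjects)
        self.norms = norms
        self.aliases = aliases
        self.binarize = binarize
        self.window_samples = window_samples

    def subject_timeseries(self) -> tuple[dict[str, list[RSATimeSeries]], list[str], dict]:
        """Per-condition per-subject semantic fits.

        Returns (series per condition, excluded subject ids, per-subject
        unmatched-trial counts).
        """
        per_cond: dict[str, list[RSATimeSeries]] = {c: [] for c in CONDITIONS}
        excluded: list[str] = []
        unmatched: dict[str, int] = {}
        for s in self.subjects:
            matches = match_concepts(s.trials, self.norms, self.aliases)
            unmatched[s.subject_id] = int((~matches["matched"]).sum())
            models = {}
            try:
                for cond in CONDITIONS:
                    models[cond] = build_semantic_rdm(
                        s.trials, matches, self.norms, cond, binarize=self.binarize
                    )
            except ValidationError as exc:
                logger.warning("excluding subject %s from semantic analysis: %s", s.subject_id, exc)
                excluded.append(s.subject_id)
                continue
            for cond in CONDITIONS:
                # restrict the epochs to the model's trials before computing
                # neural RDMs; identical to subsetting the full series
                keep_ids = set(models[cond].labels)
                sub = s.kept()
                mask = sub.trials["trial_id"].isin(keep_ids).to_numpy()
                sub = dataclasses.replace(
                    sub, data=sub.data[mask], trials=sub.trials.loc[mask].reset_index(drop=True)
                )
                series = neural_rdm_series(sub, self.window_samples)
                per_cond[cond].append(
                    rsa_timeseries(series, models[cond], subject_id=s.subject_id)
                )
        if excluded:
            logger.warning("semantic analysis excluded %d subjects: %s", len(excluded), excluded)
        return per_cond, excluded, unmatched

    def fit(
        self, alpha: float = 0.01, n_perm: int = 10000, seed: int = 0, tail: str = "two"
    ) -> SemanticRSAResults:
        per_cond, excluded, unmatched = self.subject_timeseries()
        n_usable = len(per_cond["congruent"])
        if n_usable < 3:
            raise ValidationError(
                f"semantic analysis has {n_usable} usable subjects (< 3); "
                f"excluded: {excluded}"
            )
        subject_ids = [t.subject_id for t in per_cond["congruent"]]
        rho_con = np.stack([t.rho for t in per_cond["congruent"]])
        rho_incon = np.stack([t.rho for t in per_cond["incongruent"]])
        res_con = signflip_cluster_test(
            rho_con, times=self.times, alpha=alpha, n_perm=n_perm, seed=seed,
            subject_ids=subject_ids, label="semantic/congruent", tail=tail,
        )
        res_incon = signflip_cluster_test(
            rho_incon, times=self.times, alpha=alpha, n_perm=n_perm, seed=seed + 1,
            subject_ids=subject_ids, label="semantic/incongruent", tail=tail,
        )
        res_diff = paired_cluster_test(
            rho_incon, rho_con, times=self.times, alpha=alpha, n_perm=n_perm, seed=seed + 2,
            subject_ids=subject_ids, label="semantic/incongruent-congruent", tail=tail,
        )
        return SemanticRSAResults(
            congruent=res_con,
            incongruent=res_incon,
            difference=res_diff,
            excluded_subjects=excluded,
            unmatched_counts=unmatched,
        )
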