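"""Synthetic cohorts with known representational geometry.

The generator emulates the study design this pipeline targets: a
counterbalanced cohort in which every scene appears once per participant
with either a congruent or an incongruent object (76 trials per condition
at the default 152 scenes), sparse non-negative concept × feature property
norms, and multichannel epochs in which a target representational geometry
is injected into chosen latency windows at a controllable SNR.

Signals are built from Gaussian white noise (optionally AR(1) in time)
plus two kinds of planted pattern:

* a *congruency* signal — one fixed random channel pattern per subject,
  added with +amplitude on congruent and −amplitude on incongruent trials
  inside the congruency window, so at high SNR the neural RDM matches the
  binary congruency model exactly;
* a *semantic* signal — each trial's concept feature vector pushed through
  a fixed random channel projection (per subject), added inside that
  condition's semantic window, so the neural pattern geometry mirrors the
  cosine structure of the norms.

Window edges are softened with a one-grid-step linear ramp.  Everything is
deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import EpochSet, FeatureNorms, validate_trial_table
from .exceptions import DesignError, ValidationError
from . import io as crio


@dataclass
class SimConfig:
    """Parameters of a simulated cohort.

    Defaults mirror the target study design: 152 scenes (76 per condition),
    64 channels, epochs −200..900 ms at 5 ms (200 Hz), and norms at the
    scale of a published property-norm set (826 concepts × 3026 features,
    ~15 features per concept).  Amplitudes are in µV against ``noise_sd``
    µV of sensor noise; effect windows in ms.
    """

    n_subjects: int = 20
    n_scenes: int = 152
    n_channels: int = 64
    tmin_ms: float = -200.0
    tmax_ms: float = 900.0
    tstep_ms: float = 5.0
    n_concepts: int = 826
    n_features: int = 3026
    feature_density: float = 0.005
    n_categories: int = 8
    category_mixing: float = 0.5
    congruency_window_ms: tuple[float, float] = (290.0, 450.0)
    congruency_amplitude: float = 1.0
    semantic_window_congruent_ms: tuple[float, float] = (150.0, 235.0)
    semantic_window_incongruent_ms: tuple[float, float] = (150.0, 360.0)
    semantic_amplitude_congruent: float = 1.0
    semantic_amplitude_incongruent: float = 1.0
    noise_sd: float = 1.0
    ar1_coefficient: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scenes % 2:
            raise DesignError(f"n_scenes must be even; got {self.n_scenes}")
        if not 0 < self.feature_density < 1:
            raise DesignError(f"feature_density must be in (0, 1); got {self.feature_density}")
        for name in ("congruency_amplitude", "semantic_amplitude_congruent",
                     "semantic_amplitude_incongruent"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")
        for name in ("congruency_window_ms", "semantic_window_congruent_ms",
                     "semantic_window_incongruent_ms"):
            w = tuple(float(v) for v in getattr(self, name))
            setattr(self, name, w)
            if not (self.tmin_ms <= w[0] <= w[1] <= self.tmax_ms):
                raise DesignError(f"{name}={w} outside the time grid")

    @property
    def times(self) -> np.ndarray:
        n = int(round((self.tmax_ms - self.tmin_ms) / self.tstep_ms)) + 1
        return self.tmin_ms + self.tstep_ms * np.arange(n)

    @property
    def sfreq(self) -> float:
        return 1000.0 / self.tstep_ms

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for k in ("congruency_window_ms", "semantic_window_congruent_ms",
                  "semantic_window_incongruent_ms"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _subject_seed(seed: int, index: int) -> int:
    # stable per-subject stream, kept below 2**31
    return int((seed * 1_000_003 + 7919 * (index + 1)) % (2**31 - 1))


def generate_design(
    n_scenes: int, group: str, seed: int, n_concepts: int = 826
) -> pd.DataFrame:
    """Counterbalanced trial table for one participant.

    Each scene appears exactly once; half the scenes carry their congruent
    object and half their incongruent one.  Group ``B`` receives the
    complementary condition assignment of group ``A`` for every scene.
    Scene ``i`` draws its congruent object from concept index ``2i`` and
    its incongruent object from ``2i + 1`` (modulo the concept pool), so
    the two objects of a scene are always distinct concepts.
    """
    if n_scenes % 2:
        raise DesignError(f"n_scenes must be even; got {n_scenes}")
    if group not in ("A", "B"):
        raise DesignError(f"group must be 'A' or 'B'; got {group!r}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_scenes)
    congruent_in_a = np.zeros(n_scenes, dtype=bool)
    congruent_in_a[order[: n_scenes // 2]] = True
    congruent = congruent_in_a if group == "A" else ~congruent_in_a
    presentation = rng.permutation(n_scenes)
    rows = []
    for trial_id, scene in enumerate(presentation):
        is_con = congruent[scene]
        concept_idx = (2 * scene + (0 if is_con else 1)) % n_concepts
        rows.append(
            {
                "trial_id": trial_id,
                "scene_id": f"scene_{scene:04d}",
                "object_label": f"concept_{concept_idx:04d}",
                "condition": "congruent" if is_con else "incongruent",
                "keep": True,
            }
        )
    return validate_trial_table(pd.DataFrame(rows), require_unique_scenes=True)


def generate_feature_norms(
    n_concepts: int,
    n_features: int,
    density: float,
    seed: int,
    n_categories: int = 0,
    category_mixing: float = 0.0,
) -> FeatureNorms:
    """Sparse binary concept × feature norms, optionally with planted
    category structure.

    Entries are i.i.d. Bernoulli(density); all-zero concept rows are
    resampled.  With ``n_categories`` > 0, concepts are assigned round-robin
    to latent categories, each category owning a disjoint block of
    signature features whose Bernoulli probability is boosted to
    ``density + mixing · (1 − density)``, so within-category cosine
    distances are smaller than between-category ones in expectation.
    """
    if not 0 < density < 1:
        raise DesignError(f"density must be in (0, 1); got {density}")
    if density * n_features < 1:
        raise DesignError(
            f"expected features per concept {density * n_features:.2f} < 1; infeasible"
        )
    rng = np.random.default_rng(seed)
    prob = np.full((n_concepts, n_features), density)
    if n_categories > 0:
        if not 0 <= category_mixing <= 1:
            raise DesignError("category_mixing must be in [0, 1]")
        sig_size = max(1, int(round(density * n_features)))
        if n_categories * sig_size > n_features:
            raise DesignError(
                f"{n_categories} categories × {sig_size} signature features exceed "
                f"{n_features} features"
            )
        boosted = density + category_mixing * (1.0 - density)
        for c in range(n_categories):
            members = np.arange(n_concepts) % n_categories == c
            block = slice(c * sig_size, (c + 1) * sig_size)
            prob[members, block] = boosted
    values = (rng.random((n_concepts, n_features)) < prob).astype(float)
    for i in range(n_concepts):
        while not values[i].any():
            values[i] = (rng.random(n_features) < prob[i]).astype(float)
    concepts = [f"concept_{i:04d}" for i in range(n_concepts)]
    features = [f"feature_{j:04d}" for j in range(n_features)]
    return FeatureNorms(concepts, features, values)


def _window_envelope(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """1.0 inside the closed window, 0 outside, with the first and last
    in-window samples at 0.5 (a one-grid-step linear on/off ramp)."""
    sel = (times >= window[0]) & (times <= window[1])
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        raise ValidationError(f"window {window} contains no grid points")
    env = sel.astype(float)
    env[idx[0]] = 0.5
    env[idx[-1]] = 0.5
    return env


def generate_epochs(
    config: SimConfig,
    design: pd.DataFrame,
    norms: FeatureNorms,
    subject_id: str,
    seed: int,
) -> EpochSet:
    """One participant's epochs: Gaussian noise plus planted geometry.

    All of the design's object labels must resolve in the norms.  The
    testable contract: in expectation the congruency model fit is positive
    only inside the congruency window, and each condition's semantic model
    fit is positive only inside that condition's semantic window.
    """
    missing = [lab for lab in design["object_label"] if lab not in norms]
    if missing:
        raise ValidationError(f"design labels not resolvable in norms: {sorted(set(missing))[:5]}")
    times = config.times
    n_trials, n_ch, n_t = len(design), config.n_channels, times.size
    rng = np.random.default_rng(seed)

    data = rng.normal(0.0, config.noise_sd, size=(n_trials, n_ch, n_t)) if config.noise_sd > 0 \
        else np.zeros((n_trials, n_ch, n_t))
    if config.ar1_coefficient:
        phi = config.ar1_coefficient
        if not -1 < phi < 1:
            raise DesignError(f"ar1_coefficient must be in (-1, 1); got {phi}")
        from scipy.signal import lfilter

        data = lfilter([np.sqrt(1 - phi**2)], [1.0, -phi], data, axis=2)

    is_con = (design["condition"] == "congruent").to_numpy()

    if config.congruency_amplitude > 0:
        pattern = rng.standard_normal(n_ch)
        pattern /= np.linalg.norm(pattern)
        env = _window_envelope(times, config.congruency_window_ms)
        polarity = np.where(is_con, 1.0, -1.0)
        data += (
            config.congruency_amplitude
            * polarity[:, None, None]
            * pattern[None, :, None]
            * env[None, None, :]
        )

    if config.semantic_amplitude_congruent > 0 or config.semantic_amplitude_incongruent > 0:
        projection = rng.standard_normal((n_ch, norms.n_features))
        vectors = np.stack([norms.vector(lab) for lab in design["object_label"]])
        projected = vectors @ projection.T  # (trial, channel)
        projected /= np.linalg.norm(projected, axis=1, keepdims=True)
        for cond, window, amplitude in (
            ("congruent", config.semantic_window_congruent_ms, config.semantic_amplitude_congruent),
            ("incongruent", config.semantic_window_incongruent_ms, config.semantic_amplitude_incongruent),
        ):
            if amplitude <= 0:
                continue
            env = _window_envelope(times, window)
            mask = (design["condition"] == cond).to_numpy()
            data[mask] += amplitude * projected[mask][:, :, None] * env[None, None, :]

    return EpochSet(
        subject_id=subject_id,
        data=data,
        times=times,
        channel_names=[f"EEG{c + 1:03d}" for c in range(n_ch)],
        sfreq=config.sfreq,
        trials=design,
    )


def simulate_cohort(config: SimConfig) -> tuple[FeatureNorms, list[EpochSet]]:
    """Norms plus one EpochSet per subject, counterbalanced A/B groups.

    Fully deterministic under (config, seed): subjects draw independent
    noise streams derived from the master seed, while the scene→condition
    assignment is shared (group B complementary to group A).
    """
    norms = generate_feature_norms(
        config.n_concepts, config.n_features, config.feature_density,
        seed=_subject_seed(config.seed, -1),
        n_categories=config.n_categories, category_mixing=config.category_mixing,
    )
    subjects = []
    for i in range(config.n_subjects):
        group = "A" if i % 2 == 0 else "B"
        design = generate_design(config.n_scenes, group, seed=config.seed,
                                 n_concepts=config.n_concepts)
        subjects.append(
            generate_epochs(
                config, design, norms,
                subject_id=f"sub-{i + 1:03d}",
                seed=_subject_seed(config.seed, i),
            )
        )
    return norms, subjects


def write_cohort(config: SimConfig, out_dir: str | Path) -> dict:
    """Simulate a cohort and write the epoch containers, trial TSVs and
    norms TSV to ``out_dir``.  Returns a manifest of written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    norms, subjects = simulate_cohort(config)
    norms_path = crio.write_feature_norms(norms, out_dir / "norms.tsv")
    epoch_paths = []
    for eps in subjects:
        p = crio.write_epochs(eps, out_dir / f"{eps.subject_id}_epochs.h5")
        crio.write_trial_table(eps.trials, out_dir / f"{eps.subject_id}_trials.tsv")
        epoch_paths.append(str(p))
    return {
        "norms": str(norms_path),
        "epochs": epoch_paths,
        "config": config.to_dict(),
    }
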