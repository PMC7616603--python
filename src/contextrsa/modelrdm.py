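"""Model RDMs: the binary congruency model and the semantic-feature model.

The congruency model codes each kept trial 1 (congruent) or 0 (incongruent)
and takes the Euclidean distance |c_i − c_j| between trial pairs, so
same-condition pairs get 0 and cross-condition pairs get 1.  The semantic
model represents each object by its property-norm feature vector and takes
the cosine distance between all pairs, built separately per condition.
Model RDMs are participant-specific because the counterbalanced design
gives each participant their own condition assignment per scene.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datatypes import CONDITIONS, RDM, FeatureNorms
from .exceptions import ConfigurationError, ValidationError, ZeroVarianceError

logger = logging.getLogger("contextrsa")


def build_congruency_rdm(trials: pd.DataFrame) -> RDM:
    """Binary congruency model RDM over kept trials, labelled by trial_id.

    Entry (i, j) is 0 when trials i and j share a condition and 1 otherwise
    (Euclidean distance on {0, 1} condition codes).
    """
    kept = trials.loc[trials["keep"]]
    if len(kept) < 2:
        raise ValidationError(f"congruency RDM needs at least 2 kept trials; got {len(kept)}")
    if not kept["condition"].isin(CONDITIONS).all():
        bad = kept.loc[~kept["condition"].isin(CONDITIONS)].iloc[0]
        raise ValidationError(
            f"kept trial {bad['trial_id']} has unknown condition {bad['condition']!r}"
        )
    codes = (kept["condition"] == "congruent").to_numpy(dtype=float)
    for cond in CONDITIONS:
        if not (kept["condition"] == cond).any():
            logger.warning("congruency RDM is degenerate: no %s trials", cond)
    matrix = np.abs(codes[:, None] - codes[None, :])
    return RDM(list(kept["trial_id"]), matrix, "euclidean")


def match_concepts(
    trials: pd.DataFrame,
    norms: FeatureNorms,
    aliases: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Match each trial's object label to a norms concept, deterministically.

    Matching is (1) exact case-insensitive label equality against the
    concept list, else (2) lookup in the user-supplied alias table, else
    unmatched.  No fuzzy matching: exclusions must be auditable.

    Returns
    -------
    DataFrame
        Columns trial_id, object_label, matched_concept (None when
        unmatched), matched (bool).

    Raises
    ------
    ConfigurationError
        If an alias points at a concept absent from the norms.
    """
    aliases = {str(k).strip().lower(): str(v).strip().lower() for k, v in (aliases or {}).items()}
    for label, concept in aliases.items():
        if concept not in norms:
            raise ConfigurationError(
                f"alias {label!r} -> {concept!r} targets a concept absent from the norms"
            )
    rows = []
    for trial_id, label in zip(trials["trial_id"], trials["object_label"]):
        key = str(label).strip().lower()
        if key in norms:
            concept = key
        elif key in aliases:
            concept = aliases[key]
        else:
            concept = None
        rows.append(
            {
                "trial_id": trial_id,
                "object_label": label,
                "matched_concept": concept,
                "matched": concept is not None,
            }
        )
    out = pd.DataFrame(rows)
    n_un = int((~out["matched"]).sum())
    if n_un:
        logger.info(
            "concept matching: %d/%d objects unmatched: %s",
            n_un, len(out), sorted(out.loc[~out["matched"], "object_label"].unique())[:10],
        )
    return out


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine distance 1 − u·v/(‖u‖‖v‖); in [0, 1] for non-negative vectors.

    Raises
    ------
    ZeroVarianceError
        If either vector has no positive entry (undefined angle).
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ZeroVarianceError("cosine distance undefined for a zero vector")
    return float(1.0 - float(u @ v) / (nu * nv))


def build_semantic_rdm(
    trials: pd.DataFrame,
    matches: pd.DataFrame,
    norms: FeatureNorms,
    condition: str,
    binarize: bool = False,
) -> RDM:
    """Cosine-distance semantic RDM over matched, kept trials of one condition.

    Labels carry trial_ids (in trial-table order) so the neural RDM series
    can be subset to exactly the same items.  ``binarize`` thresholds the
    feature vectors at value > 0 before computing distances.
    """
    if condition not in CONDITIONS:
        raise ValidationError(f"unknown condition {condition!r}")
    m = trials.merge(matches[["trial_id", "matched_concept", "matched"]], on="trial_id")
    sel = m.loc[m["keep"] & m["matched"] & (m["condition"] == condition)]
    if len(sel) < 2:
        raise ValidationError(
            f"semantic RDM for condition {condition!r} needs >= 2 matched kept trials; "
            f"got {len(sel)}"
        )
    vectors = np.stack([norms.vector(c) for c in sel["matched_concept"]])
    if binarize:
        vectors = (vectors > 0).astype(float)
    matrix = squareform(pdist(vectors, metric="cosine"))
    np.fill_diagonal(matrix, 0.0)
    matrix = np.clip(0.5 * (matrix + matrix.T), 0.0, 1.0)
    return RDM(list(sel["trial_id"]), matrix, "cosine")
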