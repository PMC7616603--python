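"""Readers and writers for the epoch container, norms tables and result files.

The interchange format for epoched EEG is a small HDF5 layout:

* ``/data``      — float64, (trial, channel, time), amplitudes in µV
* ``/times``     — float64, milliseconds
* ``/channels``  — UTF-8 strings
* ``/trials/*``  — one dataset per trial-table column
* root attributes ``subject_id`` and ``sfreq``

Amplitudes are stored at full 64-bit precision so that a write → read
round-trip reproduces an :class:`~contextrsa.datatypes.EpochSet` bit-exactly.
Feature norms travel as TSV, either long form (``concept  feature  value``)
or wide matrix form with a header row of feature names; the form is
auto-detected from the header.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import h5py
import numpy as np
import pandas as pd

from .datatypes import TRIAL_COLUMNS, EpochSet, FeatureNorms, RSATimeSeries
from .exceptions import FormatError

_STR = h5py.string_dtype(encoding="utf-8")


def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """Write an EpochSet to the HDF5 epoch container. Returns the path."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, dtype=np.float64)
        f.create_dataset("times", data=epochs.times, dtype=np.float64)
        f.create_dataset("channels", data=np.array(epochs.channel_names, dtype=object), dtype=_STR)
        f.attrs["subject_id"] = epochs.subject_id
        f.attrs["sfreq"] = float(epochs.sfreq)
        g = f.create_group("trials")
        t = epochs.trials
        g.create_dataset("trial_id", data=t["trial_id"].to_numpy(np.int64))
        for col in ("scene_id", "object_label", "condition"):
            g.create_dataset(col, data=t[col].to_numpy(object), dtype=_STR)
        g.create_dataset("keep", data=t["keep"].to_numpy(bool))
    return path


def read_epochs(path: str | Path) -> EpochSet:
    """Read an EpochSet from the HDF5 epoch container.

    Raises
    ------
    FormatError
        Naming the missing dataset or the mismatching shapes.
    ValidationError
        If the contents violate an EpochSet invariant (non-finite data,
        unknown condition, non-uniform times, ...).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"epoch container {path} does not exist")
    with h5py.File(path, "r") as f:
        for name in ("data", "times", "channels", "trials"):
            if name not in f:
                raise FormatError(f"epoch container {path} is missing dataset /{name}")
        data = np.asarray(f["data"], dtype=np.float64)
        times = np.asarray(f["times"], dtype=np.float64)
        channels = [c.decode() if isinstance(c, bytes) else str(c) for c in f["channels"][()]]
        g = f["trials"]
        for col in TRIAL_COLUMNS:
            if col not in g:
                raise FormatError(f"epoch container {path} is missing /trials/{col}")
        trials = pd.DataFrame(
            {
                "trial_id": np.asarray(g["trial_id"], dtype=np.int64),
                "scene_id": _decode(g["scene_id"][()]),
                "object_label": _decode(g["object_label"][()]),
                "condition": _decode(g["condition"][()]),
                "keep": np.asarray(g["keep"], dtype=bool),
            }
        )
        subject_id = str(f.attrs.get("subject_id", path.stem))
        sfreq = float(f.attrs["sfreq"])
    if data.ndim != 3:
        raise FormatError(f"/data in {path} must be 3-D (trial, channel, time); got shape {data.shape}")
    if len(trials) != data.shape[0]:
        raise FormatError(
            f"/trials in {path} has {len(trials)} rows but /data has {data.shape[0]} trials"
        )
    return EpochSet(
        subject_id=subject_id,
        data=data,
        times=times,
        channel_names=channels,
        sfreq=sfreq,
        trials=trials,
    )


def _decode(arr) -> list[str]:
    return [x.decode() if isinstance(x, bytes) else str(x) for x in arr]


# ---------------------------------------------------------------------------
# trial tables and alias tables (TSV)
# ---------------------------------------------------------------------------

def write_trial_table(trials: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    trials.loc[:, list(TRIAL_COLUMNS)].to_csv(path, sep="\t", index=False)
    return path


def read_trial_table(path: str | Path) -> pd.DataFrame:
    from .datatypes import validate_trial_table

    df = pd.read_csv(path, sep="\t", dtype={"scene_id": str, "object_label": str, "condition": str})
    return validate_trial_table(df)


def read_alias_table(path: str | Path) -> dict[str, str]:
    """Read an ``object_label<TAB>concept`` alias table into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["object_label", "concept"], dtype=str)
    return {
        str(k).strip().lower(): str(v).strip().lower()
        for k, v in zip(df["object_label"], df["concept"])
    }


# ---------------------------------------------------------------------------
# feature norms (TSV, long or wide)
# ---------------------------------------------------------------------------

_LONG_HEADER = ["concept", "feature", "value"]


def read_feature_norms(path: str | Path) -> FeatureNorms:
    """Read property norms from TSV (long or wide form, auto-detected).

    Long form has the exact header ``concept\\tfeature\\tvalue``; anything
    else is treated as a wide matrix whose first column holds concept names
    and whose remaining header cells name features.  Duplicate (concept,
    feature) pairs, negative values and all-zero concepts are errors.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if [h.strip().lower() for h in header] == _LONG_HEADER:
        df = pd.read_csv(path, sep="\t", dtype={"concept": str, "feature": str})
        df["concept"] = df["concept"].str.strip().str.lower()
        df["value"] = df["value"].astype(float)
        if (df["value"] < 0).any():
            row = df.loc[df["value"] < 0].iloc[0]
            raise FormatError(
                f"negative norm value {row['value']} for concept {row['concept']!r}, "
                f"feature {row['feature']!r}"
            )
        dup = df.duplicated(subset=["concept", "feature"])
        if dup.any():
            row = df.loc[dup].iloc[0]
            raise FormatError(
                f"duplicate (concept, feature) pair ({row['concept']!r}, {row['feature']!r})"
            )
        wide = df.pivot(index="concept", columns="feature", values="value").fillna(0.0)
        return FeatureNorms(list(wide.index), list(wide.columns), wide.to_numpy())
    # wide matrix form
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise FormatError(
            f"negative norm value for concept {df.index[i]!r}, feature {df.columns[j]!r}"
        )
    concepts = [str(c).strip().lower() for c in df.index]
    if len(set(concepts)) != len(concepts):
        raise FormatError("duplicate concept rows after case normalisation")
    return FeatureNorms(concepts, [str(c) for c in df.columns], values)


def write_feature_norms(norms: FeatureNorms, path: str | Path, form: str = "wide") -> Path:
    path = Path(path)
    if form == "wide":
        pd.DataFrame(norms.values, index=norms.concepts, columns=norms.features).to_csv(
            path, sep="\t", index_label="concept"
        )
    elif form == "long":
        rows = np.argwhere(norms.values != 0)
        pd.DataFrame(
            {
                "concept": [norms.concepts[i] for i, _ in rows],
                "feature": [norms.features[j] for _, j in rows],
                "value": [norms.values[i, j] for i, j in rows],
            }
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown norms form {form!r}")
    return path


# ---------------------------------------------------------------------------
# result files
# ---------------------------------------------------------------------------

def write_rsa_timeseries_tsv(
    series: Iterable[tuple[RSATimeSeries, str, str]], path: str | Path
) -> Path:
    """Write RSA time series to TSV with columns
    subject_id, time_ms, model, condition, rho.

    Parameters
    ----------
    series
        Iterable of ``(timeseries, model, condition)`` triples.
    """
    path = Path(path)
    frames = []
    for ts, model, condition in series:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": ts.subject_id,
                    "time_ms": ts.times,
                    "model": model,
                    "condition": condition,
                    "rho": ts.rho,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    return path


def write_cluster_report_json(report: Mapping, path: str | Path) -> Path:
    """Write a cluster report as deterministic, sorted-key JSON."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
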