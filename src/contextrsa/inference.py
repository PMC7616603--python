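"""Group-level RSA inference.

Per subject, the model fit is the Spearman rank correlation between the
strictly-lower triangles of the model RDM and the neural RDM at each
timepoint.  At the group level a one-sample t-test against zero is formed
per timepoint; contiguous runs of suprathreshold t-values (|t| above the
two-tailed critical value at the cluster-forming alpha, split at sign
changes) become clusters whose mass is the sum of t-values.  Family-wise
error across time is controlled with a max-statistic sign-flip permutation
test: each permutation flips the sign of whole per-subject time series
independently, and the maximum absolute cluster mass enters the null
distribution.  A cluster's p-value is

    p = (#{permutation maxima >= |observed mass|} + 1) / (n_perm + 1),

i.e. the observed statistic is counted as a member of its own reference
set, so p is never smaller than 1/(n_perm + 1).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .datatypes import RDM, ClusterResult, GroupRSAResult, NeuralRDMSeries, RSATimeSeries
from .exceptions import ValidationError, ZeroVarianceError


# ---------------------------------------------------------------------------
# Spearman model fit
# ---------------------------------------------------------------------------

def spearman_rho(rdm_a: RDM, rdm_b: RDM) -> float:
    """Spearman rank correlation of two RDMs' strictly-lower triangles.

    Ties get average ranks.  Labels must be identical and in identical
    order; at least 3 item pairs are required.
    """
    if rdm_a.labels != rdm_b.labels:
        raise ValidationError("RDM labels differ (or are ordered differently)")
    a, b = rdm_a.triangle(), rdm_b.triangle()
    if a.size < 3:
        raise ValidationError(f"Spearman needs >= 3 item pairs; got {a.size}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ZeroVarianceError("Spearman undefined: an RDM triangle is constant")
    return float(stats.spearmanr(a, b).statistic)


def rsa_timeseries(series: NeuralRDMSeries, model: RDM, subject_id: str = "") -> RSATimeSeries:
    """Spearman model fit at every timepoint of a neural RDM series.

    The series is automatically subset (and reordered) to the model's
    labels, so a per-condition model RDM can be related directly to the
    full-trial neural series.
    """
    if list(series.labels) != list(model.labels):
        series = series.subset(model.labels)
    X = series.triangles()  # (n_times, n_pairs)
    m = model.triangle()
    if m.size < 3:
        raise ValidationError(f"Spearman needs >= 3 item pairs; got {m.size}")
    if np.ptp(m) == 0:
        raise ZeroVarianceError("model RDM triangle is constant; Spearman undefined")
    flat = np.ptp(X, axis=1) == 0
    if flat.any():
        tp = int(np.flatnonzero(flat)[0])
        raise ZeroVarianceError(
            f"neural RDM triangle constant at timepoint index {tp} "
            f"({series.times[tp]:g} ms); Spearman undefined"
        )
    rm = stats.rankdata(m)
    rX = stats.rankdata(X, axis=1)
    rm = rm - rm.mean()
    rX = rX - rX.mean(axis=1, keepdims=True)
    rho = (rX @ rm) / (np.linalg.norm(rX, axis=1) * np.linalg.norm(rm))
    return RSATimeSeries(subject_id, series.times, np.clip(rho, -1.0, 1.0))


# ---------------------------------------------------------------------------
# group statistics and clusters
# ---------------------------------------------------------------------------

def group_tvalues(rhos: np.ndarray) -> np.ndarray:
    """One-sample t against zero per timepoint: mean / (sd / sqrt(n)), ddof 1.

    A timepoint with zero variance yields ±inf (sign of the mean), which
    exceeds any cluster-forming threshold; zero mean with zero variance
    yields t = 0.
    """
    rhos = np.asarray(rhos, dtype=np.float64)
    if rhos.ndim != 2 or rhos.shape[0] < 3:
        raise ValidationError("group t-test needs a (n_subjects >= 3, n_times) matrix")
    if not np.isfinite(rhos).all():
        raise ValidationError("missing/non-finite subject rho values; exclude subjects listwise first")
    n = rhos.shape[0]
    mean = rhos.mean(axis=0)
    sd = rhos.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(np.isnan(t), 0.0, t)


def cluster_forming_threshold(df: int, alpha: float, tail: str = "two") -> float:
    """Critical t at the cluster-forming alpha (two-tailed by default)."""
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1); got {alpha}")
    if tail not in ("two", "pos"):
        raise ValidationError(f"tail must be 'two' or 'pos'; got {tail!r}")
    q = 1.0 - alpha / 2.0 if tail == "two" else 1.0 - alpha
    return float(stats.t.ppf(q, df))


def find_clusters(
    tvalues: np.ndarray, df: int, alpha: float, times: np.ndarray | None = None,
    tail: str = "two",
) -> list[ClusterResult]:
    """Contiguous runs where |t| exceeds the critical value, split at sign
    changes; mass = sum of t within the run.  Empty list if none.  With
    ``tail='pos'`` only positive runs above the one-tailed threshold count."""
    tvalues = np.asarray(tvalues, dtype=np.float64)
    thr = cluster_forming_threshold(df, alpha, tail)
    if times is None:
        times = np.arange(tvalues.size, dtype=float)
    supra = (np.abs(tvalues) > thr) if tail == "two" else (tvalues > thr)
    sign = np.sign(tvalues)
    clusters: list[ClusterResult] = []
    i, n = 0, tvalues.size
    while i < n:
        if not supra[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and supra[j + 1] and sign[j + 1] == sign[i]:
            j += 1
        clusters.append(
            ClusterResult(
                start_time=float(times[i]),
                end_time=float(times[j]),
                start_index=i,
                end_index=j,
                mass=float(tvalues[i : j + 1].sum()),
            )
        )
        i = j + 1
    return clusters


def _max_cluster_masses(tmat: np.ndarray, threshold: float, tail: str = "two") -> np.ndarray:
    """Per row of (n_perm, n_times) t-values, the maximum |cluster mass|
    over suprathreshold sign-homogeneous runs; 0.0 for rows with none."""
    n_perm, n_times = tmat.shape
    out = np.zeros(n_perm)
    for s in (1.0, -1.0) if tail == "two" else (1.0,):
        vals = s * tmat
        mask = vals > threshold
        if not mask.any():
            continue
        contrib = np.where(mask, vals, 0.0).ravel()
        prev = np.empty_like(mask)
        prev[:, 0] = False
        prev[:, 1:] = mask[:, :-1]
        starts = np.flatnonzero((mask & ~prev).ravel())
        sums = np.add.reduceat(contrib, starts)
        np.maximum.at(out, starts // n_times, sums)
    return out


def signflip_cluster_test(
    rhos: np.ndarray,
    times: np.ndarray | None = None,
    alpha: float = 0.01,
    n_perm: int = 10000,
    seed: int = 0,
    subject_ids: list[str] | None = None,
    label: str = "",
    tail: str = "two",
) -> GroupRSAResult:
    """One-sample cluster-mass permutation test with per-subject sign flips.

    Parameters
    ----------
    rhos
        (n_subjects, n_times) matrix of per-subject model-fit time series.
    times
        Time axis in ms (indices if omitted).
    alpha
        Cluster-forming alpha for the t threshold.
    n_perm
        Number of random sign-flip permutations (>= 1).
    seed
        Seed for the permutation generator; required for reproducibility.
    tail
        ``two`` (default): two-tailed threshold, signed clusters, null
        distribution of the maximum absolute cluster mass.  ``pos``:
        one-tailed threshold, positive clusters only.
    """
    rhos = np.asarray(rhos, dtype=np.float64)
    if n_perm < 1:
        raise ValidationError(f"n_perm must be >= 1; got {n_perm}")
    n = rhos.shape[0]
    if times is None:
        times = np.arange(rhos.shape[1], dtype=float)
    tvals = group_tvalues(rhos)
    df = n - 1
    thr = cluster_forming_threshold(df, alpha, tail)
    clusters = find_clusters(tvals, df, alpha, times, tail)

    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n)).astype(np.float64) * 2.0 - 1.0
    mean = (signs @ rhos) / n
    sumsq = np.einsum("st,st->t", rhos, rhos)  # invariant under sign flips
    var = np.maximum(sumsq[None, :] - n * mean**2, 0.0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tmat = mean / np.sqrt(var / n)
    tmat = np.where(np.isnan(tmat), 0.0, tmat)
    perm_max = _max_cluster_masses(tmat, thr, tail)

    for c in clusters:
        m = abs(c.mass)
        # ">=" with a float-tie guard: a permutation that reproduces the
        # observed sign pattern recomputes the same mass up to rounding
        exceed = int(np.sum((perm_max >= m) | np.isclose(perm_max, m, rtol=1e-9, atol=1e-12)))
        c.p_value = (exceed + 1) / (n_perm + 1)

    if subject_ids is None:
        subject_ids = [f"sub-{i:03d}" for i in range(n)]
    return GroupRSAResult(
        times=times,
        rho=rhos,
        subject_ids=subject_ids,
        tvalues=tvals,
        clusters=clusters,
        n_permutations=n_perm,
        alpha_cluster_forming=alpha,
        cluster_forming_threshold=thr,
        seed=seed,
        label=label,
    )


def paired_cluster_test(
    rhos_a: np.ndarray,
    rhos_b: np.ndarray,
    times: np.ndarray | None = None,
    alpha: float = 0.01,
    n_perm: int = 10000,
    seed: int = 0,
    subject_ids: list[str] | None = None,
    label: str = "",
    tail: str = "two",
) -> GroupRSAResult:
    """Paired cluster-mass permutation test on per-subject differences.

    Equivalent (bit-exact at fixed seed) to the one-sample sign-flip test
    applied to ``rhos_a − rhos_b``; flipping a subject's sign corresponds
    to swapping that subject's condition labels.
    """
    rhos_a = np.asarray(rhos_a, dtype=np.float64)
    rhos_b = np.asarray(rhos_b, dtype=np.float64)
    if rhos_a.shape != rhos_b.shape:
        raise ValidationError(
            f"paired test needs matching subject × time matrices; got {rhos_a.shape} vs {rhos_b.shape}"
        )
    return signflip_cluster_test(
        rhos_a - rhos_b, times=times, alpha=alpha, n_perm=n_perm, seed=seed,
        subject_ids=subject_ids, label=label, tail=tail,
    )


# ---------------------------------------------------------------------------
# time-course correlation
# ---------------------------------------------------------------------------

def timecourse_correlation(
    x: np.ndarray,
    y: np.ndarray,
    times: np.ndarray | None = None,
    window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Pearson correlation between two model-fit time courses.

    Returns (r, p) with the two-tailed p from the t distribution with
    n − 2 degrees of freedom.  ``window`` is a closed ms interval on the
    time axis; the full epoch is used when omitted.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValidationError("time courses must have equal length")
    if window is not None:
        if times is None:
            raise ValidationError("a window requires a time axis")
        times = np.asarray(times, dtype=np.float64)
        sel = (times >= window[0]) & (times <= window[1])
        x, y = x[sel], y[sel]
    if x.size < 3:
        raise ValidationError(f"correlation needs >= 3 timepoints; got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("correlation undefined for a constant time course")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
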