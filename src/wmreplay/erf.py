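"""Event-related field contrast between PM and non-PM stimuli at encoding.

Each encoding epoch is tagged by whether its stimulus turned out to be the
predominantly maintained (PM) item of its trial.  Per subject, PM and
non-PM average ERFs are computed from 20 Hz low-passed, whole-epoch
baseline-corrected epochs; their difference is tested at the group level
over the full channels x time grid with a spatio-temporal cluster
permutation (within-subject condition-label sign flipping, max cluster
mass), which controls familywise error without parametric smoothness
assumptions.  Channel adjacency comes from a configurable neighborhood
graph; for simulated data a synthetic planar sensor layout is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats

from .containers import SensorEpochs, ValidationError

__all__ = [
    "ErfStatMap",
    "synthetic_sensor_layout",
    "channel_adjacency",
    "subject_erf_difference",
    "erf_contrast_from_differences",
    "compute_erf_contrast",
]


def synthetic_sensor_layout(n_channels: int) -> np.ndarray:
    """Deterministic 2-D sensor positions on a sunflower (Fibonacci) disc.

    A stand-in layout for simulated data, where no physical helmet
    geometry exists; it provides a plausible planar neighborhood structure.
    """
    k = np.arange(n_channels)
    golden = (1 + 5**0.5) / 2
    r = np.sqrt((k + 0.5) / n_channels)
    theta = 2 * np.pi * k / golden**2
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def channel_adjacency(
    positions: np.ndarray, n_neighbors: int = 4
) -> sparse.coo_matrix:
    """Symmetric k-nearest-neighbor adjacency over sensor positions."""
    n = positions.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 channels for adjacency")
    d2 = ((positions[:, None, :] - positions[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    k = min(n_neighbors, n - 1)
    adj = np.zeros((n, n), dtype=bool)
    nearest = np.argsort(d2, axis=1)[:, :k]
    rows = np.repeat(np.arange(n), k)
    adj[rows, nearest.ravel()] = True
    adj |= adj.T
    return sparse.coo_matrix(adj)


def subject_erf_difference(
    epochs: SensorEpochs, pm_column: str = "is_pm"
) -> np.ndarray:
    """PM-minus-non-PM average ERF for one subject (channels x time).

    The PM and non-PM averages come from disjoint epoch sets by
    construction (the flag partitions the epochs); a subject lacking either
    condition raises and should be excluded upstream.
    """
    if pm_column not in epochs.events:
        raise ValidationError(f"events lack a {pm_column!r} column")
    flags = epochs.events[pm_column].to_numpy().astype(bool)
    if flags.all() or not flags.any():
        raise ValidationError("subject lacks PM or non-PM epochs")
    return epochs.data[flags].mean(axis=0) - epochs.data[~flags].mean(axis=0)


@dataclass
class ErfStatMap:
    """Group-level channels x time statistics for the PM/non-PM contrast."""

    f_map: np.ndarray  # (n_channels, n_times)
    times_ms: np.ndarray
    channel_ids: list[str]
    clusters: list[tuple[np.ndarray, np.ndarray]]  # (time idx, channel idx)
    cluster_p_values: list[float]
    peaks: list[dict] = field(default_factory=list)
    alpha: float = 0.05
    n_permutations: int = 2000
    n_subjects_excluded: int = 0
    method: str = (
        "within-subject PM/non-PM difference; spatio-temporal cluster "
        "permutation (sign flip, max cluster mass)"
    )

    @property
    def significant_clusters(self) -> list[int]:
        return [i for i, p in enumerate(self.cluster_p_values) if p < self.alpha]


def erf_contrast_from_differences(
    diffs: list[np.ndarray],
    times_ms: np.ndarray,
    channel_ids: list[str] | None = None,
    adjacency: sparse.spmatrix | None = None,
    n_permutations: int = 2000,
    cluster_alpha: float = 0.05,
    alpha: float = 0.05,
    seed: int = 0,
    n_subjects_excluded: int = 0,
) -> ErfStatMap:
    """Cluster-permutation test on per-subject (channels x time) differences.

    The F map is the squared one-sample t statistic of the differences, so
    it matches a two-level (within-subject contrast, between-subject random
    effects) F test with one numerator degree of freedom.
    """
    from mne.stats import spatio_temporal_cluster_1samp_test

    if len(diffs) < 2:
        raise ValidationError("need >= 2 subjects with both conditions")
    # (n_subjects, n_times, n_channels) for the spatio-temporal test
    X = np.stack(diffs).transpose(0, 2, 1)
    df = X.shape[0] - 1
    thresh = stats.t.ppf(1 - cluster_alpha / 2, df)
    n_channels = X.shape[2]
    if channel_ids is None:
        channel_ids = [f"CH{i:03d}" for i in range(n_channels)]
    if adjacency is None:
        adjacency = channel_adjacency(synthetic_sensor_layout(n_channels))
    t_obs, clusters, cluster_pv, _ = spatio_temporal_cluster_1samp_test(
        X,
        threshold=thresh,
        n_permutations=n_permutations,
        tail=0,
        adjacency=adjacency.tocoo(),
        seed=seed,
        out_type="indices",
        verbose=False,
    )
    f_map = (np.asarray(t_obs) ** 2).T  # back to channels x time
    keep_clusters = [(np.asarray(c[0]), np.asarray(c[1])) for c in clusters]
    pvals = [float(p) for p in cluster_pv]
    peaks = []
    for (t_idx, ch_idx), p in zip(keep_clusters, pvals):
        if p >= alpha:
            continue
        vals = f_map[ch_idx, t_idx]
        i = int(np.argmax(vals))
        peaks.append(
            {
                "channel": channel_ids[int(ch_idx[i])],
                "time_ms": float(np.asarray(times_ms)[int(t_idx[i])]),
                "F": float(vals[i]),
                "cluster_p": p,
            }
        )
    return ErfStatMap(
        f_map=f_map,
        times_ms=np.asarray(times_ms, float).copy(),
        channel_ids=list(channel_ids),
        clusters=keep_clusters,
        cluster_p_values=pvals,
        peaks=peaks,
        alpha=alpha,
        n_permutations=n_permutations,
        n_subjects_excluded=n_subjects_excluded,
    )


def compute_erf_contrast(
    epochs_by_subject: list[SensorEpochs],
    pm_column: str = "is_pm",
    adjacency: sparse.spmatrix | None = None,
    n_permutations: int = 2000,
    cluster_alpha: float = 0.05,
    alpha: float = 0.05,
    seed: int = 0,
) -> ErfStatMap:
    """Cluster-permutation test of the PM vs non-PM evoked difference.

    Inputs must already be low-pass filtered (20 Hz) and whole-epoch
    baseline corrected (see :mod:`wmreplay.preprocess`).  Subjects with
    zero PM or zero non-PM epochs are excluded (counted in the result).
    """
    diffs = []
    n_excluded = 0
    template: SensorEpochs | None = None
    for ep in epochs_by_subject:
        try:
            diffs.append(subject_erf_difference(ep, pm_column))
            template = ep
        except ValidationError:
            n_excluded += 1
    if template is None or len(diffs) < 2:
        raise ValidationError("need >= 2 subjects with both conditions")
    return erf_contrast_from_differences(
        diffs,
        times_ms=template.time_ms,
        channel_ids=template.channel_ids,
        adjacency=adjacency,
        n_permutations=n_permutations,
        cluster_alpha=cluster_alpha,
        alpha=alpha,
        seed=seed,
        n_subjects_excluded=n_excluded,
    )
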