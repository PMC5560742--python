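"""Margin-thresholded state decoding of retention and ITI periods.

The classifiers from the best encoding bin slide over 20 ms bins of the
delay-period data.  Each bin gets a single label: the category favored by
the pairwise classifier whose decision value lies farthest from its
boundary, with the winning absolute margin recorded as the confidence
distance ``d``.  A conservative quantile threshold ``d*`` — chosen so that
``1 - reliability`` of the *retention-period* bins fall below it — then
relabels low-confidence bins as N (null / no replay).  The same threshold
is applied to the ITI control window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    BIN_MS,
    CATEGORIES,
    ITI_WINDOW_MS,
    NULL_LABEL,
    RETENTION_WINDOW_MS,
    SensorEpochs,
    ValidationError,
)
from .encoding import PAIRS, PairwiseClassifier, TimeBinGrid, extract_bin_features

__all__ = [
    "WindowBins",
    "RejectionThreshold",
    "DecodedSequence",
    "define_analysis_windows",
    "decode_bin",
    "decode_period",
    "compute_rejection_threshold",
    "apply_threshold",
]

_CAT_RANK = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class WindowBins:
    """An analysis window partitioned into 20 ms decoding bins."""

    period: str  # "retention" | "iti"
    window_ms: tuple[float, float]
    centers_ms: tuple[float, ...]

    @property
    def n_bins(self) -> int:
        return len(self.centers_ms)


def _window_bins(period: str, window: tuple[float, float]) -> WindowBins:
    start, end = window
    n = int(round((end - start) / BIN_MS))
    if n < 1:
        raise ValidationError(f"window {window} shorter than one bin")
    centers = tuple(start + BIN_MS / 2 + i * BIN_MS for i in range(n))
    return WindowBins(period, window, centers)


def define_analysis_windows(
    retention_window: tuple[float, float] = RETENTION_WINDOW_MS,
    iti_window: tuple[float, float] = ITI_WINDOW_MS,
) -> tuple[WindowBins, WindowBins]:
    """Retention and ITI analysis windows, each cut into 20 ms bins.

    Defaults: retention = [1000, 4000) ms after the last stimulus offset
    (skipping offset-evoked activity), ITI = [-3000, 0) ms before the first
    stimulus onset; 150 bins each.
    """
    return _window_bins("retention", retention_window), _window_bins(
        "iti", iti_window
    )


def _margins(
    classifiers: dict[tuple[str, str], PairwiseClassifier], features: np.ndarray
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    pairs = [p for p in PAIRS if p in classifiers]
    if len(pairs) != 3:
        raise ValidationError("need all three pairwise classifiers")
    m = np.column_stack(
        [classifiers[p].decision_values(features) for p in pairs]
    )
    return m, pairs


def decode_features(
    classifiers: dict[tuple[str, str], PairwiseClassifier], features: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized label + distance for each row of ``features``.

    The label is the category favored by the pairwise decision of largest
    absolute value; ``d`` is that absolute value.  Exact ties go to the
    earliest category in the order F < B < C (a zero margin favors neither
    side of its pair, so an all-zero bin decodes as F with d = 0 and is
    rejected by any positive threshold).
    """
    m, pairs = _margins(classifiers, features)
    absm = np.abs(m)
    d = absm.max(axis=1)
    # favored category rank per classifier column
    first = np.array([_CAT_RANK[p[0]] for p in pairs])
    second = np.array([_CAT_RANK[p[1]] for p in pairs])
    fav_rank = np.where(m > 0, first[None, :], second[None, :])
    tied = absm >= d[:, None] - 1e-300
    rank = np.where(tied, fav_rank, 99).min(axis=1)
    labels = np.array(CATEGORIES)[rank]
    labels = np.where(d == 0, CATEGORIES[0], labels)
    return labels, d


def decode_bin(
    classifiers: dict[tuple[str, str], PairwiseClassifier], features: np.ndarray
) -> tuple[str, float]:
    """Decode a single bin's feature vector; returns ``(raw_label, d)``."""
    labels, d = decode_features(classifiers, np.atleast_2d(features))
    return str(labels[0]), float(d[0])


def decode_period(
    classifiers: dict[tuple[str, str], PairwiseClassifier],
    epochs: SensorEpochs,
    window: WindowBins,
    grid: TimeBinGrid | None = None,
) -> pd.DataFrame:
    """Decode every 20 ms bin of every epoch in an analysis window.

    Returns one row per (trial, bin): ``trial_id, period, bin_index,
    raw_label, d``.
    """
    if grid is None:
        grid = TimeBinGrid(window.centers_ms, BIN_MS, epochs.fs)
    trial_ids = epochs.events["trial_id"].to_numpy()
    frames = []
    for bi, center in enumerate(window.centers_ms):
        X = extract_bin_features(epochs, grid, center)
        labels, d = decode_features(classifiers, X)
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": trial_ids,
                    "period": window.period,
                    "bin_index": bi,
                    "raw_label": labels,
                    "d": d,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["trial_id", "bin_index"], kind="stable").reset_index(
        drop=True
    )


@dataclass(frozen=True)
class RejectionThreshold:
    """The d* quantile threshold derived from retention-period distances."""

    d_star: float
    target_rejection_fraction: float
    n_records: int
    source_period: str = "retention"


def compute_rejection_threshold(
    retention_records: pd.DataFrame | np.ndarray, reliability: float
) -> RejectionThreshold:
    """d* such that a fraction ``1 - reliability`` of retention bins fall
    strictly below it.

    If the classifiers are reliable 78% of the time, the 22% least confident
    retention labels are rejected.  The threshold is the lower empirical
    quantile (a ranked order statistic, no interpolation), so on the
    defining set the rejected fraction equals the target to within one rank
    position.
    """
    if not 0 < reliability <= 1:
        raise ValidationError("reliability must be in (0, 1]")
    d = (
        retention_records["d"].to_numpy()
        if isinstance(retention_records, pd.DataFrame)
        else np.asarray(retention_records, float)
    )
    if d.size == 0:
        raise ValidationError("no retention records to derive d* from")
    frac = 1.0 - reliability
    s = np.sort(d)
    k = int(np.floor(d.size * frac + 1e-12))
    d_star = float(s[k]) if k < d.size else float(np.inf)
    return RejectionThreshold(
        d_star=d_star, target_rejection_fraction=frac, n_records=int(d.size)
    )


@dataclass(frozen=True)
class DecodedSequence:
    """Per-trial, per-period label sequence over {F, B, C, N} with margins."""

    trial_id: int
    period: str
    labels: tuple[str, ...]
    distances: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.distances):
            raise ValidationError("labels and distances misaligned")


def apply_threshold(
    records: pd.DataFrame, threshold: RejectionThreshold
) -> list[DecodedSequence]:
    """Relabel bins with ``d < d_star`` as N; assemble per-trial sequences.

    The same (retention-derived) conservative threshold is applied to
    whichever period the records come from.
    """
    rec = records.copy()
    rec["label"] = np.where(
        rec["d"].to_numpy() < threshold.d_star, NULL_LABEL, rec["raw_label"]
    )
    out: list[DecodedSequence] = []
    for (tid, period), g in rec.groupby(["trial_id", "period"], sort=True):
        g = g.sort_values("bin_index")
        out.append(
            DecodedSequence(
                trial_id=int(tid),
                period=str(period),
                labels=tuple(g["label"]),
                distances=tuple(float(x) for x in g["d"]),
            )
        )
    return out


def rejection_fraction(seqs: list[DecodedSequence]) -> float:
    """Fraction of bins labeled N across a set of decoded sequences."""
    n = sum(len(s.labels) for s in seqs)
    if n == 0:
        raise ValidationError("no decoded bins")
    rej = sum(lab == NULL_LABEL for s in seqs for lab in s.labels)
    return rej / n
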