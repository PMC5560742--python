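"""Time-bin-resolved pairwise linear decoding of stimulus category.

During encoding, each presented stimulus evokes a category-specific spatial
pattern.  Three pairwise linear max-margin classifiers (F-B, F-C, B-C) are
trained on 20 ms bins of the broadband sensor amplitude (13 samples x
channels features per bin), with per-fold univariate t-test feature
reduction and z-score normalization learned on training folds only, and
evaluated by stratified 10-fold cross-validation.  Group-level significance
against the 50% chance level is assessed with a sign-flip max-cluster-mass
permutation test over the accuracy curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .containers import CATEGORIES, SensorEpochs, ValidationError

__all__ = [
    "PAIRS",
    "TimeBinGrid",
    "PairwiseClassifier",
    "AccuracyCurve",
    "make_time_bins",
    "extract_bin_features",
    "reduce_features",
    "train_pairwise_classifier",
    "crossvalidate_bins",
    "group_accuracy_significance",
    "select_best_bin",
]

#: The three category pairs, each ordered by the canonical category order
#: F < B < C.  A positive decision value favors the first element.
PAIRS: tuple[tuple[str, str], ...] = (("F", "B"), ("F", "C"), ("B", "C"))

_CAT_RANK = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class TimeBinGrid:
    """Uniform grid of decoding bins.

    Each bin of ``width_ms`` is indexed by its center and spans
    ``[center - width/2, center + width/2]`` inclusive, hence
    ``samples_per_bin = floor(width * fs / 1000) + 1`` (13 at 20 ms/600 Hz).
    """

    centers_ms: tuple[float, ...]
    width_ms: float
    fs: float

    @property
    def samples_per_bin(self) -> int:
        return int(np.floor(self.width_ms * self.fs / 1000.0)) + 1

    @property
    def n_bins(self) -> int:
        return len(self.centers_ms)


def make_time_bins(
    t_start: float = -20.0,
    t_end: float = 500.0,
    width: float = 20.0,
    fs: float = 600.0,
) -> TimeBinGrid:
    """Bins covering ``[t_start, t_end)``: centers at ``t_start + width/2``,
    stepping by ``width``.  Defaults give the 26 encoding bins centered at
    -10, 10, ..., 490 ms."""
    if width <= 0 or fs <= 0:
        raise ValidationError("width and fs must be positive")
    if t_end - t_start < width:
        raise ValidationError("window shorter than one bin")
    centers = np.arange(t_start + width / 2.0, t_end, width)
    return TimeBinGrid(tuple(float(c) for c in centers), float(width), float(fs))


def extract_bin_features(
    epochs: SensorEpochs, grid: TimeBinGrid, center_ms: float
) -> np.ndarray:
    """Feature matrix (epochs x features) for one bin.

    Features are the raw amplitudes of the ``samples_per_bin`` samples of
    every channel, flattened channel-major (all samples of channel 0, then
    channel 1, ...), giving ``channels x samples_per_bin`` features
    (274 x 13 = 3562 with the defaults).
    """
    spb = grid.samples_per_bin
    start = center_ms - grid.width_ms / 2.0
    i0 = epochs.sample_index(start)
    if i0 + spb > epochs.n_samples:
        raise ValidationError(
            f"bin centered at {center_ms} ms extends past the epoch"
        )
    block = epochs.data[:, :, i0 : i0 + spb]
    return block.reshape(epochs.n_epochs, epochs.n_channels * spb)


def reduce_features(
    train_features: np.ndarray, train_labels: np.ndarray, alpha: float = 0.05
) -> np.ndarray:
    """Univariate feature screen on training data only.

    Keeps features whose two-sample two-tailed t-test between the two
    classes has p < ``alpha``.  If nothing survives (possible on null data
    at small alpha), the single smallest-p feature is kept so a classifier
    can still be fit.
    """
    labels = np.asarray(train_labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValidationError(f"need exactly 2 classes, got {classes.size}")
    a = train_features[labels == classes[0]]
    b = train_features[labels == classes[1]]
    _, p = stats.ttest_ind(a, b, axis=0)
    p = np.nan_to_num(p, nan=1.0)
    mask = p < alpha
    if not mask.any():
        mask[np.argmin(p)] = True
    return mask


@dataclass
class PairwiseClassifier:
    """A trained linear max-margin classifier for one category pair and bin.

    Stores everything needed to score unseen bins: the training-fold feature
    mask, per-feature center/scale, and the hyperplane.  Decision values are
    signed so that a positive value favors ``pair[0]`` (the pair is ordered
    by the canonical category order F < B < C).
    """

    pair: tuple[str, str]
    bin_center_ms: float
    feature_mask: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    weights: np.ndarray
    bias: float

    def decision_values(self, features: np.ndarray) -> np.ndarray:
        """Signed margins for a (epochs x features) matrix."""
        if features.shape[1] != self.feature_mask.size:
            raise ValidationError(
                f"expected {self.feature_mask.size} features, "
                f"got {features.shape[1]}"
            )
        x = (features[:, self.feature_mask] - self.center) / self.scale
        return x @ self.weights + self.bias

    def predict(self, features: np.ndarray) -> np.ndarray:
        dv = self.decision_values(features)
        return np.where(dv > 0, self.pair[0], self.pair[1])


def _ordered_pair(pair: tuple[str, str]) -> tuple[str, str]:
    return tuple(sorted(pair, key=_CAT_RANK.get))  # type: ignore[return-value]


def train_pairwise_classifier(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    bin_center_ms: float,
    pair: tuple[str, str],
    alpha: float = 0.05,
    C: float = 1.0,
) -> PairwiseClassifier:
    """Fit the normalize -> reduce -> linear-SVM pipeline on one bin.

    Requires balanced classes (equal trial counts); callers downsample
    first.  Normalization statistics and the feature screen come from the
    training data only and are stored for application to unseen data.
    """
    pair = _ordered_pair(pair)
    labels = np.asarray(train_labels)
    n0 = int((labels == pair[0]).sum())
    n1 = int((labels == pair[1]).sum())
    if n0 == 0 or n1 == 0:
        raise ValidationError(f"both classes of {pair} must be present")
    if n0 != n1:
        raise ValidationError(
            f"unbalanced classes for {pair}: {n0} vs {n1}; downsample first"
        )
    mask = reduce_features(train_features, labels, alpha=alpha)
    x = train_features[:, mask]
    center = x.mean(axis=0)
    scale = x.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    xz = (x - center) / scale
    svm = SVC(kernel="linear", C=C)
    svm.fit(xz, labels)
    w = svm.coef_.ravel().astype(np.float64)
    b = float(svm.intercept_[0])
    # sklearn's positive decision side is classes_[1]; flip so that positive
    # favors pair[0] under the canonical category order.
    if svm.classes_[1] != pair[0]:
        w, b = -w, -b
    return PairwiseClassifier(
        pair=pair,
        bin_center_ms=float(bin_center_ms),
        feature_mask=mask,
        center=center,
        scale=scale,
        weights=w,
        bias=b,
    )


@dataclass
class AccuracyCurve:
    """Cross-validated accuracies per (pair, bin) plus the per-bin mean."""

    bin_centers_ms: tuple[float, ...]
    pairs: tuple[tuple[str, str], ...]
    accuracy: np.ndarray  # (n_pairs, n_bins)
    fold_counts: tuple[int, ...] = ()

    @property
    def mean_accuracy(self) -> np.ndarray:
        return self.accuracy.mean(axis=0)

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, p in enumerate(self.pairs):
            for j, c in enumerate(self.bin_centers_ms):
                rows.append(
                    {"pair": "-".join(p), "bin_center_ms": c,
                     "accuracy": self.accuracy[i, j]}
                )
        return pd.DataFrame(rows)


def _balanced_subset(
    labels: np.ndarray, classes: tuple[str, str], rng: np.random.Generator
) -> np.ndarray:
    """Indices of a seeded random downsample to the smaller class size."""
    idx_by_class = [np.flatnonzero(labels == c) for c in classes]
    n = min(len(ix) for ix in idx_by_class)
    if n == 0:
        raise ValidationError(f"no trials for one of {classes}")
    keep = [rng.choice(ix, size=n, replace=False) for ix in idx_by_class]
    return np.sort(np.concatenate(keep))


def crossvalidate_bins(
    epochs: SensorEpochs,
    grid: TimeBinGrid,
    folds: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
    C: float = 1.0,
) -> AccuracyCurve:
    """Stratified k-fold CV of every pairwise classifier at every bin.

    Classes are balanced by seeded downsampling to the smallest class
    before CV.  Feature reduction and normalization are re-learned inside
    each training fold.  Accuracy is the mean over folds; the per-bin mean
    over the three pairs is exposed via :attr:`AccuracyCurve.mean_accuracy`.
    """
    if "category" not in epochs.events:
        raise ValidationError("epochs.events must contain a 'category' column")
    labels_all = epochs.events["category"].to_numpy()
    rng = np.random.default_rng(seed)
    feats_by_bin = {
        c: extract_bin_features(epochs, grid, c) for c in grid.centers_ms
    }
    acc = np.zeros((len(PAIRS), grid.n_bins))
    for pi, pair in enumerate(PAIRS):
        sel = _balanced_subset(labels_all, pair, rng)
        labels = labels_all[sel]
        n_per_class = (labels == pair[0]).sum()
        if n_per_class < folds:
            raise ValidationError(
                f"need >= {folds} trials per category, got {n_per_class}"
            )
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        splits = list(skf.split(np.zeros(len(sel)), labels))
        for bi, center in enumerate(grid.centers_ms):
            X = feats_by_bin[center][sel]
            fold_acc = []
            for tr, te in splits:
                # re-balance the training fold exactly (stratification can
                # leave a 1-trial imbalance)
                tr_bal = tr[
                    _balanced_subset(
                        labels[tr], pair, np.random.default_rng(seed + bi)
                    )
                ]
                clf = train_pairwise_classifier(
                    X[tr_bal], labels[tr_bal], center, pair, alpha=alpha, C=C
                )
                pred = clf.predict(X[te])
                fold_acc.append(float((pred == labels[te]).mean()))
            acc[pi, bi] = float(np.mean(fold_acc))
    return AccuracyCurve(
        bin_centers_ms=grid.centers_ms,
        pairs=PAIRS,
        accuracy=acc,
        fold_counts=(folds,) * len(PAIRS),
    )


@dataclass
class GroupSignificance:
    """Group-level test of accuracy curves against chance."""

    bin_centers_ms: tuple[float, ...]
    t_values: np.ndarray
    significant: np.ndarray  # boolean per bin
    cluster_p_values: list[float]
    clusters: list[np.ndarray]
    method: str = (
        "one-sample t vs chance; FWE by sign-flip max-cluster-mass permutation"
    )


def _cluster_indices(cl, n: int) -> np.ndarray:
    """Normalize a permutation-test cluster (mask, slice or indices)."""
    if isinstance(cl, tuple):
        cl = cl[0]
    if isinstance(cl, slice):
        return np.arange(n)[cl]
    arr = np.asarray(cl)
    if arr.dtype == bool:
        return np.flatnonzero(arr)
    return arr.astype(int)


def group_accuracy_significance(
    curves: list[AccuracyCurve],
    chance: float = 0.5,
    n_permutations: int = 5000,
    cluster_alpha: float = 0.05,
    alpha: float = 0.05,
    seed: int = 0,
) -> GroupSignificance:
    """Test per-bin mean accuracy across subjects against chance.

    Familywise error over the bin dimension is controlled by a sign-flip
    permutation of subject-level deviations from chance with a
    max-cluster-mass statistic (cluster-forming threshold from a one-sided
    t at ``cluster_alpha``); the cluster approach respects the temporal
    smoothness of the accuracy curve.
    """
    from mne.stats import permutation_cluster_1samp_test

    if len(curves) < 2:
        raise ValidationError("need at least 2 subjects")
    centers = curves[0].bin_centers_ms
    X = np.stack([c.mean_accuracy for c in curves]) - chance
    df = X.shape[0] - 1
    thresh = stats.t.ppf(1 - cluster_alpha, df)
    t_obs, clusters, cluster_pv, _ = permutation_cluster_1samp_test(
        X,
        threshold=thresh,
        n_permutations=n_permutations,
        tail=1,
        stat_fun=None,
        seed=seed,
        out_type="mask",
        verbose=False,
    )
    n_bins = X.shape[1]
    sig = np.zeros(n_bins, dtype=bool)
    keep_clusters, keep_p = [], []
    for cl, p in zip(clusters, cluster_pv):
        idx = _cluster_indices(cl, n_bins)
        keep_clusters.append(idx)
        keep_p.append(float(p))
        if p < alpha:
            sig[idx] = True
    return GroupSignificance(
        bin_centers_ms=centers,
        t_values=np.asarray(t_obs),
        significant=sig,
        cluster_p_values=keep_p,
        clusters=keep_clusters,
    )


def select_best_bin(
    curve: AccuracyCurve,
    epochs: SensorEpochs | None = None,
    grid: TimeBinGrid | None = None,
    seed: int = 0,
    alpha: float = 0.05,
    C: float = 1.0,
) -> tuple[float, dict[tuple[str, str], PairwiseClassifier] | None]:
    """Bin with maximal mean-over-pairs CV accuracy (ties -> earliest bin).

    When ``epochs`` (and its ``grid``) are provided, the three pairwise
    classifiers are refit on *all* encoding trials at the selected bin
    (balanced by seeded downsampling) and returned for delay decoding.
    """
    if len(curve.bin_centers_ms) == 0:
        raise ValidationError("empty accuracy curve")
    mean_acc = curve.mean_accuracy
    best = int(np.argmax(mean_acc))  # argmax returns the earliest maximum
    center = curve.bin_centers_ms[best]
    if epochs is None:
        return center, None
    if grid is None:
        grid = TimeBinGrid(curve.bin_centers_ms, 20.0, epochs.fs)
    X = extract_bin_features(epochs, grid, center)
    labels = epochs.events["category"].to_numpy()
    rng = np.random.default_rng(seed)
    classifiers = {}
    for pair in PAIRS:
        sel = _balanced_subset(labels, pair, rng)
        classifiers[pair] = train_pairwise_classifier(
            X[sel], labels[sel], center, pair, alpha=alpha, C=C
        )
    return center, classifiers
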