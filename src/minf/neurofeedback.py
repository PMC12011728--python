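"""Online neurofeedback quantities: log-power features, the LDA classifier
triplet, border calibration and feedback ball position.

Features are log band powers of 1-s bins with 0.9375-s overlap. At 500 Hz
that hop is 31.25 samples, so bin onsets advance by floor(i * fs/16) samples,
alternating 31- and 32-sample steps so the average overlap is exact.

Three classifiers steer the ball: LR (left- vs right-hand MI) drives the
horizontal axis (lateralization; positive score = right-hand evidence) and
BaseL / BaseR (contralateral MI vs baseline activity per hand) drive the
vertical axis. Each classifier's border is the upper quartile of its held-out
cross-validation scores for the target state; scores divided by borders and
clipped to [-1, 1] give the on-screen coordinates, so left-hand success sends
the ball to the upper-left corner and right-hand success to the upper-right.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from minf.preprocessing import EpochSet

MI_SEGMENT = (0.5, 4.5)
BASELINE_SEGMENT = (-7.0, -3.0)

POWER_FLOOR = 1e-20


@dataclass
class FeatureSet:
    """Log band-power features: trials x bins x feature dims."""

    bins: np.ndarray               # (n_trials, n_bins, n_features)
    bin_onsets: np.ndarray         # s, relative to MI onset
    labels: np.ndarray             # class label per trial
    trial_ids: np.ndarray          # globally unique trial identifiers
    segment: str                   # 'MI' | 'baseline'

    @property
    def n_trials(self) -> int:
        return self.bins.shape[0]

    @property
    def n_bins(self) -> int:
        return self.bins.shape[1]

    def relabel(self, label: str) -> "FeatureSet":
        import dataclasses

        return dataclasses.replace(
            self, labels=np.array([label] * self.n_trials, dtype=object)
        )


@dataclass
class LinearClassifier:
    """Linear discriminant with decision score s(x) = w . x + b.

    Positive score = evidence for ``positive_label``. ``cv_scores`` and
    ``cv_labels`` hold held-out decision scores from cross-validation;
    ``fold_accuracies`` the per-fold accuracy.
    """

    weights: np.ndarray
    bias: float
    positive_label: str
    negative_label: str
    fold_accuracies: np.ndarray = field(default_factory=lambda: np.array([]))
    cv_scores: np.ndarray = field(default_factory=lambda: np.array([]))
    cv_labels: np.ndarray = field(default_factory=lambda: np.array([]))

    def score(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x) @ self.weights + self.bias

    @property
    def cv_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())


@dataclass
class ClassifierTriplet:
    """LR, BaseL, BaseR classifiers with their calibrated borders."""

    LR: LinearClassifier
    BaseL: LinearClassifier
    BaseR: LinearClassifier
    borders: dict                  # {'LR': float, 'BaseL': float, 'BaseR': float}
    trained_on_run: str = ""


def bin_onset_samples(segment_samples: int, bin_samples: int, fs: float,
                      hop_s: float = 0.0625) -> np.ndarray:
    """Integer bin onsets realizing the fractional hop exactly on average."""
    onsets = []
    i = 0
    while True:
        s0 = int(np.floor(i * hop_s * fs))
        if s0 + bin_samples > segment_samples:
            break
        onsets.append(s0)
        i += 1
    return np.array(onsets, dtype=int)


def extract_features(ep: EpochSet, segment: str = "MI",
                     mi_window: tuple[float, float] = MI_SEGMENT,
                     baseline_window: tuple[float, float] = BASELINE_SEGMENT,
                     bin_dur: float = 1.0, hop: float = 0.0625) -> FeatureSet:
    """Sliding log-power features over the MI or baseline segment.

    Each feature dimension is log(mean squared amplitude) of one channel in
    one 1-s bin. All-zero bins are floored at a tiny epsilon with a warning.
    """
    window = mi_window if segment == "MI" else baseline_window
    sl = ep.sample_slice(window)
    seg = ep.data[:, :, sl]
    bin_samples = int(round(bin_dur * ep.fs))
    onsets = bin_onset_samples(seg.shape[-1], bin_samples, ep.fs, hop)
    if onsets.size == 0:
        raise ValueError("segment shorter than one bin")
    power = np.stack(
        [np.mean(seg[:, :, s0:s0 + bin_samples] ** 2, axis=2) for s0 in onsets],
        axis=1,
    )  # (trials, bins, channels)
    if (power <= 0).any():
        warnings.warn("non-positive bin power floored at epsilon")
        power = np.maximum(power, POWER_FLOOR)
    return FeatureSet(
        bins=np.log(power),
        bin_onsets=window[0] + onsets / ep.fs,
        labels=ep.labels.copy(),
        trial_ids=ep.trial_index.copy(),
        segment=segment,
    )


def _grouped_stratified_folds(trial_ids: np.ndarray, labels: np.ndarray,
                              k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold id per trial: trials dealt round-robin within each label stratum.

    A trial id appearing under both labels (MI and baseline bins of the same
    trial) is assigned once, keeping all its bins in one fold.
    """
    uniq, first = np.unique(trial_ids, return_index=True)
    strata = labels[first]
    fold_of = {}
    for lab in np.unique(strata):
        ids = uniq[strata == lab]
        ids = ids[~np.isin(ids, list(fold_of))]
        perm = rng.permutation(len(ids))
        for j, tid in enumerate(ids[perm]):
            fold_of[tid] = j % k
    return np.array([fold_of[t] for t in trial_ids])


def train_lda_cv(features_a: FeatureSet, features_b: FeatureSet, k: int = 7,
                 shrinkage: float = 0.05, seed: int = 0) -> LinearClassifier:
    """LDA with k-fold CV stratified by class and grouped by trial.

    All bins of a trial stay in one fold (overlapping bins would otherwise
    leak between folds). Returns the classifier refit on all data together
    with fold accuracies and held-out decision scores. Positive score =
    evidence for features_b's label.
    """
    for f in (features_a, features_b):
        n_cls = len(np.unique(f.trial_ids))
        if k > n_cls:
            raise ValueError(f"k={k} exceeds class trial count {n_cls}")
    lab_a = features_a.labels[0]
    lab_b = features_b.labels[0]
    if lab_a == lab_b:
        raise ValueError("the two feature sets must carry distinct labels")

    def flat(f):
        n_feat = f.bins.shape[2]
        X = f.bins.reshape(-1, n_feat)
        y = np.repeat(f.labels, f.n_bins)
        g = np.repeat(f.trial_ids, f.n_bins)
        return X, y, g

    Xa, ya, ga = flat(features_a)
    Xb, yb, gb = flat(features_b)
    X = np.vstack([Xa, Xb])
    y = np.concatenate([ya, yb])
    groups = np.concatenate([ga, gb])

    rng = np.random.default_rng(seed)
    per_trial_ids = np.concatenate([features_a.trial_ids, features_b.trial_ids])
    per_trial_labels = np.concatenate([features_a.labels, features_b.labels])
    fold_of_trial = _grouped_stratified_folds(per_trial_ids, per_trial_labels, k, rng)
    fold_map = dict(zip(per_trial_ids, fold_of_trial))
    folds = np.array([fold_map[g] for g in groups])

    def make_lda():
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)

    accs, scores, score_labels = [], [], []
    for f in range(k):
        test = folds == f
        if len(np.unique(y[~test])) < 2:
            raise ValueError("a CV fold lost one class entirely; reduce k")
        lda = make_lda().fit(X[~test], y[~test])
        accs.append(lda.score(X[test], y[test]))
        s = lda.decision_function(X[test])
        if lda.classes_[1] != lab_b:   # orient: positive = lab_b evidence
            s = -s
        scores.append(s)
        score_labels.append(y[test])

    final = make_lda().fit(X, y)
    w = final.coef_.ravel()
    b = float(final.intercept_[0])
    if final.classes_[1] != lab_b:
        w, b = -w, -b
    return LinearClassifier(
        weights=w,
        bias=b,
        positive_label=lab_b,
        negative_label=lab_a,
        fold_accuracies=np.array(accs),
        cv_scores=np.concatenate(scores),
        cv_labels=np.concatenate(score_labels),
    )


def compute_border(clf: LinearClassifier, cv_scores: np.ndarray | None = None,
                   cv_labels: np.ndarray | None = None,
                   pooled: bool = False) -> float:
    """Border = Q3 (linear interpolation) of held-out target-class scores.

    ``pooled=True`` instead takes Q3 over all held-out scores regardless of
    class; the default uses the classifier's target (positive) class only.
    """
    scores = clf.cv_scores if cv_scores is None else np.asarray(cv_scores)
    labels = clf.cv_labels if cv_labels is None else np.asarray(cv_labels)
    if scores.size == 0:
        raise ValueError("no cross-validation scores to compute a border from")
    if not pooled:
        if labels.size == scores.size:
            target = scores[labels == clf.positive_label]
            if target.size:
                scores = target
    return float(np.percentile(scores, 75))


def train_classifier_triplet(mi_features: FeatureSet,
                             baseline_features: FeatureSet,
                             k: int = 7, shrinkage: float = 0.05,
                             seed: int = 0, run: str = "") -> ClassifierTriplet:
    """Train LR, BaseL, BaseR on one run's features and calibrate borders.

    LR separates left- from right-hand MI bins (positive = right). BaseL and
    BaseR separate each hand's MI bins from the same trials' baseline bins
    (positive = MI evidence). Borders are upper quartiles of held-out scores.
    """
    def subset(f: FeatureSet, hand: str) -> FeatureSet:
        import dataclasses

        m = f.labels == hand
        return dataclasses.replace(
            f, bins=f.bins[m], labels=f.labels[m], trial_ids=f.trial_ids[m]
        )

    left_mi = subset(mi_features, "left")
    right_mi = subset(mi_features, "right")
    lr = train_lda_cv(left_mi, right_mi, k=k, shrinkage=shrinkage, seed=seed)

    base_l = train_lda_cv(
        subset(baseline_features, "left").relabel("baseline"),
        left_mi.relabel("MI-left"),
        k=k, shrinkage=shrinkage, seed=seed + 1,
    )
    base_r = train_lda_cv(
        subset(baseline_features, "right").relabel("baseline"),
        right_mi.relabel("MI-right"),
        k=k, shrinkage=shrinkage, seed=seed + 2,
    )
    borders = {
        "LR": compute_border(lr),
        "BaseL": compute_border(base_l),
        "BaseR": compute_border(base_r),
    }
    return ClassifierTriplet(LR=lr, BaseL=base_l, BaseR=base_r,
                             borders=borders, trained_on_run=run)


def classify_stream(features: FeatureSet, triplet: ClassifierTriplet) -> dict:
    """Raw decision score per bin for each classifier: (trials, bins) arrays."""
    n_feat = features.bins.shape[2]
    for name in ("LR", "BaseL", "BaseR"):
        if getattr(triplet, name).weights.shape[0] != n_feat:
            raise ValueError(f"{name} feature dimension mismatch")
    X = features.bins.reshape(-1, n_feat)
    shape = features.bins.shape[:2]
    return {
        name: getattr(triplet, name).score(X).reshape(shape)
        for name in ("LR", "BaseL", "BaseR")
    }


def map_feedback(scores: dict, hand: str, borders: dict) -> tuple:
    """Ball position (x, y), each clipped to [-1, 1].

    x = LR score / LR border (positive = rightward); y = the trial hand's
    Base score / border (positive = upward, i.e. MI-vs-baseline evidence).
    Left-hand success therefore drives toward (-1, +1), right-hand toward
    (+1, +1).
    """
    base_key = "BaseL" if hand == "left" else "BaseR"
    for key in ("LR", base_key):
        if borders[key] == 0:
            raise ZeroDivisionError(f"zero border for {key}")
    x = float(np.clip(np.asarray(scores["LR"]) / borders["LR"], -1.0, 1.0))
    y = float(np.clip(np.asarray(scores[base_key]) / borders[base_key], -1.0, 1.0))
    return x, y


def feedback_trace(features: FeatureSet, triplet: ClassifierTriplet) -> "np.ndarray":
    """Per-bin (x, y) ball trace for every trial: (trials, bins, 2)."""
    stream = classify_stream(features, triplet)
    out = np.empty((features.n_trials, features.n_bins, 2))
    for i in range(features.n_trials):
        hand = features.labels[i]
        for j in range(features.n_bins):
            out[i, j] = map_feedback(
                {k: v[i, j] for k, v in stream.items()}, hand, triplet.borders
            )
    return out
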