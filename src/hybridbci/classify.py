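"""SVM classification under leave-one-out cross-validation, plus the
summary statistics used to compare feature sets."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from . import constants as C
from .features import FeatureSet


@dataclass
class ClassifierSpec:
    """RBF-kernel SVM parameters; gamma defaults to 1/n_features."""

    C: float = C.SVM_C
    gamma: Optional[float] = None  # None → 1 / n_features

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be > 0")

    def resolve_gamma(self, n_features: int) -> float:
        return self.gamma if self.gamma is not None else 1.0 / n_features


@dataclass
class ClassificationResult:
    predictions: np.ndarray
    labels: np.ndarray
    accuracy: float  # percent
    modality: str
    mode: str
    folds: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.predictions) != len(self.labels):
            raise ValueError("one prediction per trial required")
        if not (0.0 <= self.accuracy <= 100.0):
            raise ValueError("accuracy must be within [0, 100]")


# builder(train_idx, test_idx) -> (F_train, y_train, F_test)
FoldBuilder = Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray, np.ndarray]]


def loocv_svm(fs: FeatureSet, spec: ClassifierSpec = ClassifierSpec(),
              mode: str = "paper",
              fold_builder: Optional[FoldBuilder] = None,
              balance_folds: bool = True, seed: int = 0) -> ClassificationResult:
    """Hold out every trial once and classify it with an RBF SVM.

    In ``paper`` mode the feature matrix is used as given (normalization
    and any upstream PCA fitted once on all trials). In ``fold_safe`` mode
    a ``fold_builder`` recomputes the training-fold features and the
    held-out trial's features without it, per fold.

    ``balance_folds`` additionally drops one random other-class trial from
    each training fold so class counts stay equal (24 + 24 for 25-trial
    classes). Without it, leave-one-out with an RBF SVM on uninformative
    features collapses to the training-fold majority class, which is the
    held-out class's complement, and null accuracy sinks toward 0 % rather
    than chance.
    """
    labels = np.asarray(fs.labels)
    classes = np.unique(labels.astype(str))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if min((labels == c).sum() for c in classes) < 2:
        raise ValueError("need at least 2 trials per class")
    if mode not in ("paper", "fold_safe"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "fold_safe" and fold_builder is None:
        raise ValueError("fold_safe mode requires a fold_builder")
    rng = np.random.default_rng(seed)
    n = fs.n_trials
    preds = np.empty(n, dtype=object)
    for i in range(n):
        train = np.setdiff1d(np.arange(n), [i])
        if balance_folds:
            other = train[labels[train].astype(str) != str(labels[i])]
            train = np.setdiff1d(train, [rng.choice(other)])
        if mode == "paper":
            F_train, y_train, F_test = fs.F[train], labels[train], fs.F[[i]]
        else:
            F_train, y_train, F_test = fold_builder(train, np.array([i]))
        clf = SVC(C=spec.C, kernel="rbf", gamma=spec.resolve_gamma(F_train.shape[1]))
        clf.fit(F_train, y_train.astype(str))
        preds[i] = clf.predict(F_test)[0]
    accuracy = 100.0 * float(np.mean(preds.astype(str) == labels.astype(str)))
    return ClassificationResult(predictions=preds, labels=labels, accuracy=accuracy,
                                modality=fs.modality, mode=mode)


# ---------------------------------------------------------------------------
# statistics

#: two-sided critical interval of q = range / sd for the normality check,
#: per sample size. The n = 11 bounds are the published tabulated values;
#: the rest were frozen from a 2e6-draw Monte-Carlo estimate of the same
#: (5%, 95%) quantile convention (see tests).
WS_CRITICAL = {
    3: (1.758, 1.999),
    4: (1.979, 2.429),
    5: (2.139, 2.755),
    6: (2.281, 3.012),
    7: (2.401, 3.222),
    8: (2.503, 3.399),
    9: (2.592, 3.552),
    10: (2.670, 3.685),
    11: (2.74, 3.80),
    12: (2.805, 3.909),
    13: (2.864, 4.004),
    14: (2.918, 4.091),
    15: (2.969, 4.172),
    20: (3.177, 4.487),
}


def ws_normality(values: np.ndarray, critical: Optional[tuple[float, float]] = None
                 ) -> tuple[float, bool]:
    """Range-over-standard-deviation normality statistic.

    Returns (q, verdict) where the verdict is True when q falls inside the
    two-sided critical interval for the sample size.
    """
    v = np.asarray(values, float)
    n = len(v)
    if n < 2:
        raise ValueError("need at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation: q undefined")
    q = float((v.max() - v.min()) / sd)
    if critical is None:
        if n not in WS_CRITICAL:
            raise ValueError(f"no critical interval tabulated for n={n}")
        critical = WS_CRITICAL[n]
    lo, hi = critical
    return q, bool(lo <= q <= hi)


def paired_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, dof, p)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.all(d == 0):
        return 0.0, n - 1, 1.0
    if d.std(ddof=1) == 0:
        raise ValueError("zero-variance non-zero differences")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), n - 1, float(res.pvalue)


@dataclass
class StatsReport:
    means: dict
    stds: dict
    ws: dict        # modality -> {"q": float, "normal": bool}
    paired: dict    # "hybrid_vs_eeg" etc -> {"t", "dof", "p"}
    n: int

    def to_dict(self) -> dict:
        return {"n": self.n, "means": self.means, "stds": self.stds,
                "ws": self.ws, "paired": self.paired}


def summarize(accuracies: dict[str, np.ndarray]) -> StatsReport:
    """Means, standard deviations, normality checks and the paired
    hybrid-vs-unimodal comparisons across sessions/subjects."""
    required = {"eeg", "fnirs", "hybrid"}
    missing = required - set(accuracies)
    if missing:
        raise ValueError(f"missing modalities: {sorted(missing)}")
    arrays = {k: np.asarray(v, float) for k, v in accuracies.items()}
    lengths = {len(v) for v in arrays.values()}
    if len(lengths) != 1:
        raise ValueError("accuracy vectors must have equal length")
    n = lengths.pop()
    means = {k: float(v.mean()) for k, v in arrays.items()}
    stds = {k: float(v.std(ddof=1)) for k, v in arrays.items()}
    ws = {}
    for k, v in arrays.items():
        q, normal = ws_normality(v)
        ws[k] = {"q": q, "normal": normal}
    paired = {}
    for other in ("eeg", "fnirs"):
        t, dof, p = paired_ttest(arrays["hybrid"], arrays[other])
        paired[f"hybrid_vs_{other}"] = {"t": t, "dof": dof, "p": p}
    return StatsReport(means=means, stds=stds, ws=ws, paired=paired, n=n)
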