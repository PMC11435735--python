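"""Validation regimes, metrics and the subject x classifier x window sweep.

Two regimes mirror the study design: a stratified 70/30 train/test holdout
(with metrics reported on both portions — the train-portion numbers are the
"training" curves) and stratified 5-fold cross-validation reporting
fold-mean metrics.  Inside every training portion the full feature chain
(CSP fit and, for SVM/MLP, feature standardization) is refitted from scratch,
so no information leaks from test trials.

Metrics: accuracy = (tp + tn) / total, and the false-positive ratio
fpr = fp / (fp + tn) — the fraction of negative-class trials (rest periods,
or opposite-limb imagery) classified as the active motor-imagery class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import classify, csp
from .preprocess import EpochSet, WindowSpec, slice_epochs

logger = logging.getLogger(__name__)

REGIMES = ("holdout_70_30", "cv_5fold")

#: positive (active-MI) class per task mode; the FPR denominator is the other
POSITIVE_CLASS = {"mi_vs_rest": "mi", "left_vs_right": "right"}


@dataclass
class SplitPlan:
    """Trial-level assignment for one validation regime.

    For the holdout regime ``assignments`` holds 0 (train) / 1 (test); for
    5-fold CV it holds the test-fold index 0-4 of each trial.
    """

    regime: str
    assignments: np.ndarray
    seed: int
    stratified: bool = True

    @property
    def n_folds(self) -> int:
        return 1 if self.regime == "holdout_70_30" else int(self.assignments.max()) + 1

    def folds(self):
        """Yield (train_idx, test_idx) pairs."""
        if self.regime == "holdout_70_30":
            yield np.where(self.assignments == 0)[0], np.where(self.assignments == 1)[0]
        else:
            for k in range(self.n_folds):
                yield np.where(self.assignments != k)[0], np.where(self.assignments == k)[0]


@dataclass
class ConfusionCounts:
    """Binary confusion-matrix counts with an explicit positive class."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    positive_class: str = ""

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
            self.positive_class or other.positive_class,
        )

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvalResult:
    """One cell of the sweep: metrics for (subject, classifier, window, regime).

    ``accuracy``/``fpr`` are the test-side numbers (fold means under CV);
    the holdout regime additionally reports ``train_accuracy``/``train_fpr``
    measured on the 70% training portion.
    """

    subject_id: str
    classifier: str
    window: WindowSpec
    regime: str
    accuracy: float
    fpr: float
    counts: ConfusionCounts
    seed: int
    train_accuracy: float | None = None
    train_fpr: float | None = None
    error: str | None = None


def make_split(labels: np.ndarray, regime: str, seed: int) -> SplitPlan:
    """Stratified trial assignment for one regime, deterministic in the seed."""
    labels = np.asarray(labels)
    if regime not in REGIMES:
        raise ValueError(f"regime must be one of {REGIMES}")
    classes, counts = np.unique(labels, return_counts=True)
    if regime == "cv_5fold":
        if counts.min() < 5:
            raise ValueError(
                f"5-fold CV needs >= 5 trials per class, got {dict(zip(classes, counts))}"
            )
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        assignments = np.empty(len(labels), dtype=int)
        for k, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            assignments[test_idx] = k
    else:
        if counts.min() < 2:
            raise ValueError("holdout needs >= 2 trials per class")
        idx = np.arange(len(labels))
        _, test_idx = train_test_split(
            idx, test_size=0.3, random_state=seed, stratify=labels
        )
        assignments = np.zeros(len(labels), dtype=int)
        assignments[test_idx] = 1
    return SplitPlan(regime=regime, assignments=assignments, seed=seed)


def accuracy(counts: ConfusionCounts) -> float:
    """Fraction of correct predictions, (tp + tn) / total."""
    if counts.total == 0:
        raise ValueError("cannot compute accuracy on zero predictions")
    return (counts.tp + counts.tn) / counts.total


def false_positive_ratio(counts: ConfusionCounts) -> float:
    """Fraction of negative-class (rest-period) trials predicted positive."""
    denom = counts.fp + counts.tn
    if denom == 0:
        raise ValueError(
            "false-positive ratio undefined: no negative-class trials evaluated"
        )
    return counts.fp / denom


def _count(
    true: np.ndarray, pred: np.ndarray, positive: str
) -> ConfusionCounts:
    true = true.astype(str)
    pred = pred.astype(str)
    return ConfusionCounts(
        tp=int(np.sum((true == positive) & (pred == positive))),
        tn=int(np.sum((true != positive) & (pred != positive))),
        fp=int(np.sum((true != positive) & (pred == positive))),
        fn=int(np.sum((true == positive) & (pred != positive))),
        positive_class=positive,
    )


_FITTERS = {
    "lda": lambda feats, cfg, pos: classify.fit_lda(feats, positive_label=pos),
    "svm": lambda feats, cfg, pos: classify.fit_svm(feats, cfg, positive_label=pos),
    "mlp": lambda feats, cfg, pos: classify.fit_mlp(feats, cfg, positive_label=pos),
}


def evaluate_once(
    epochs: EpochSet,
    window: WindowSpec,
    classifier: str,
    plan: SplitPlan,
    cfg: classify.TrainConfig | None = None,
    positive_class: str | None = None,
    n_csp_pairs: int = 3,
    subject_id: str = "S01",
) -> EvalResult:
    """Fit and score one (window, classifier, split-plan) combination.

    Per training portion: slice the window, fit CSP on training trials only,
    transform both portions, fit the classifier, predict the held-out trials.
    CV returns fold-mean metrics and pooled counts.
    """
    if classifier not in _FITTERS:
        raise ValueError(f"unknown classifier {classifier!r}; choose from {tuple(_FITTERS)}")
    cfg = cfg or classify.TrainConfig()
    win_epochs = slice_epochs(epochs, window)
    labels = win_epochs.labels.astype(str)
    classes = sorted(set(labels))
    pos = positive_class if positive_class is not None else classes[-1]
    accs, fprs = [], []
    counts_sum = ConfusionCounts(positive_class=pos)
    train_acc = train_fpr = None
    for train_idx, test_idx in plan.folds():
        tr = EpochSet(
            win_epochs.data[train_idx], labels[train_idx], win_epochs.t0,
            win_epochs.fs, win_epochs.channel_labels,
        )
        te = EpochSet(
            win_epochs.data[test_idx], labels[test_idx], win_epochs.t0,
            win_epochs.fs, win_epochs.channel_labels,
        )
        neg = classes[0] if classes[1] == pos else classes[1]
        c_pos = csp.class_covariance(tr, pos)
        c_neg = csp.class_covariance(tr, neg)
        model = csp.fit_csp(c_pos, c_neg, m=n_csp_pairs)
        f_tr = csp.transform(model, tr)
        f_te = csp.transform(model, te)
        clf = _FITTERS[classifier](f_tr, cfg, pos)
        counts = _count(te.labels, classify.predict(clf, f_te), pos)
        accs.append(accuracy(counts))
        fprs.append(false_positive_ratio(counts))
        counts_sum = counts_sum + counts
        if plan.regime == "holdout_70_30":
            tc = _count(tr.labels, classify.predict(clf, f_tr), pos)
            train_acc = accuracy(tc)
            train_fpr = false_positive_ratio(tc)
    return EvalResult(
        subject_id=subject_id,
        classifier=classifier,
        window=window,
        regime=plan.regime,
        accuracy=float(np.mean(accs)),
        fpr=float(np.mean(fprs)),
        counts=counts_sum,
        seed=plan.seed,
        train_accuracy=train_acc,
        train_fpr=train_fpr,
    )


def run_sweep(
    epoch_sets: dict[str, EpochSet],
    classifiers: tuple[str, ...] = classify.CLASSIFIER_NAMES,
    windows: list[WindowSpec] | None = None,
    regimes: tuple[str, ...] = REGIMES,
    cfg: classify.TrainConfig | None = None,
    positive_class: str | None = None,
    seed: int = 0,
    n_csp_pairs: int = 3,
) -> list[EvalResult]:
    """Full cartesian sweep over subjects, classifiers, windows and regimes.

    ``epoch_sets`` maps subject id -> band-passed, segmented epochs.  A failing
    cell is recorded with its error message and the sweep continues.
    """
    from .preprocess import window_scheme

    if not epoch_sets:
        raise ValueError("sweep needs at least one subject")
    windows = windows if windows is not None else window_scheme()
    results: list[EvalResult] = []
    for subject_id, epochs in epoch_sets.items():
        plans = {
            regime: make_split(epochs.labels, regime, seed) for regime in regimes
        }
        for regime in regimes:
            for clf_name in classifiers:
                for w in windows:
                    try:
                        results.append(
                            evaluate_once(
                                epochs, w, clf_name, plans[regime], cfg,
                                positive_class=positive_class,
                                n_csp_pairs=n_csp_pairs,
                                subject_id=subject_id,
                            )
                        )
                    except Exception as exc:  # record and continue
                        logger.warning(
                            "sweep cell failed (%s, %s, %s, %s): %s",
                            subject_id, clf_name, w.name, regime, exc,
                        )
                        results.append(
                            EvalResult(
                                subject_id=subject_id, classifier=clf_name,
                                window=w, regime=regime,
                                accuracy=float("nan"), fpr=float("nan"),
                                counts=ConfusionCounts(), seed=seed,
                                error=str(exc),
                            )
                        )
    return results


def results_frame(results: list[EvalResult]) -> pd.DataFrame:
    """Tidy table: one row per EvalResult."""
    rows = []
    for r in results:
        rows.append(
            {
                "subject_id": r.subject_id,
                "classifier": r.classifier,
                "window": r.window.name,
                "duration_s": r.window.duration,
                "window_start_s": r.window.start,
                "regime": r.regime,
                "accuracy": r.accuracy,
                "fpr": r.fpr,
                "train_accuracy": r.train_accuracy,
                "train_fpr": r.train_fpr,
                "tp": r.counts.tp,
                "tn": r.counts.tn,
                "fp": r.counts.fp,
                "fn": r.counts.fn,
                "seed": r.seed,
                "error": r.error,
            }
        )
    return pd.DataFrame(rows)


def duration_summary(results: list[EvalResult] | pd.DataFrame) -> pd.DataFrame:
    """Mean metrics per (classifier, regime, duration), averaging same-duration
    windows and subjects — the per-duration curves of the study figures."""
    df = results if isinstance(results, pd.DataFrame) else results_frame(results)
    df = df[df["error"].isna()] if "error" in df else df
    out = (
        df.groupby(["classifier", "regime", "duration_s"], as_index=False)
        .agg(
            accuracy=("accuracy", "mean"),
            fpr=("fpr", "mean"),
            train_accuracy=("train_accuracy", "mean"),
            train_fpr=("train_fpr", "mean"),
            n_cells=("accuracy", "size"),
        )
        .sort_values(["classifier", "regime", "duration_s"])
        .reset_index(drop=True)
    )
    return out
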