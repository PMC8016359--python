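"""Metrics, ROC/AUC, repeated cross-validation and the independent test.

Two cross-validation protocols are provided.  Under ``protocol="paper"``
the coupling tables are fitted once on the *entire* dataset before it is
split into folds, mirroring the published validation procedure in which
feature extraction precedes the random partition.  Because every held-out
window then contributes its own counts to the probability tables, this
protocol leaks test information into the features and yields optimistic
scores.  Under ``protocol="nested"`` the tables are refitted inside each
fold on training windows only, which is the statistically sound default.

Metrics are the confusion-matrix set — sensitivity, specificity,
precision, accuracy and Matthews correlation — plus the area under the
ROC curve computed on decision scores pooled across the folds of a
repeat (the rank / Mann-Whitney formulation, ties counted half).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from . import costsvm
from .costsvm import HyperParams, TrainedModel, class_costs
from .coupling import CouplingModel, encode_windows, fit_model
from .windowing import POSITIVE, WindowDataset


class EvaluationError(ValueError):
    """Raised for inconsistent label/score inputs or degenerate datasets."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvaluationError(f"negative confusion count in {self}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Confusion-derived metrics, plus AUC when scores were available."""

    sn: float
    sp: float
    precision: float
    acc: float
    mcc: float
    auc: float | None = None

    def to_dict(self) -> dict[str, float | None]:
        return asdict(self)


@dataclass
class CVConfig:
    """Configuration of the repeated k-fold protocol."""

    folds: int = 10
    repeats: int = 10
    protocol: str = "nested"
    seed: int = 0
    per_repeat_hyperparams: list[HyperParams] | None = None

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise EvaluationError(f"folds must be >= 2, got {self.folds}")
        if self.repeats < 1:
            raise EvaluationError(f"repeats must be >= 1, got {self.repeats}")
        if self.protocol not in ("paper", "nested"):
            raise EvaluationError(f"unknown protocol {self.protocol!r}")
        if (
            self.per_repeat_hyperparams is not None
            and len(self.per_repeat_hyperparams) != self.repeats
        ):
            raise EvaluationError(
                f"{len(self.per_repeat_hyperparams)} hyperparameter entries "
                f"for {self.repeats} repeats"
            )


@dataclass
class CVResult:
    """Mean and standard deviation over repeats, with per-repeat detail."""

    mean: MetricReport
    sd: MetricReport
    per_repeat: list[MetricReport]
    hyperparams: list[HyperParams]


def confusion(
    true_labels: Sequence[int], predicted_labels: Sequence[int]
) -> ConfusionCounts:
    """Cross-tabulate +1/-1 labels against predictions."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise EvaluationError(
            f"label length mismatch: {t.shape} true vs {p.shape} predicted"
        )
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        fp=int(((t == -1) & (p == 1)).sum()),
        tn=int(((t == -1) & (p == -1)).sum()),
        fn=int(((t == 1) & (p == -1)).sum()),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den else 0.0


def metrics(counts: ConfusionCounts, auc: float | None = None) -> MetricReport:
    """Sensitivity, specificity, precision, accuracy and MCC from counts.

    Degenerate denominators (no predicted positives, a zero MCC factor)
    yield 0 rather than an error.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return MetricReport(
        sn=_ratio(tp, tp + fn),
        sp=_ratio(tn, tn + fp),
        precision=_ratio(tp, tp + fp),
        acc=_ratio(tp + tn, counts.total),
        mcc=_ratio(tp * tn - fp * fn, mcc_den),
        auc=auc,
    )


def roc_auc(true_labels: Sequence[int], scores: Sequence[float]) -> float:
    """Probability that a random positive outscores a random negative.

    Ties count one half (rank formulation); both classes must be present.
    """
    t = np.asarray(true_labels)
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape:
        raise EvaluationError("labels and scores differ in length")
    if len(set(t.tolist())) < 2:
        raise EvaluationError("AUC needs both classes present")
    return float(roc_auc_score(t, s))


def roc_points(
    true_labels: Sequence[int], scores: Sequence[float]
) -> list[tuple[float, float, float]]:
    """ROC curve as (fpr, tpr, threshold) triples for plotting or export."""
    fpr, tpr, thr = roc_curve(np.asarray(true_labels), np.asarray(scores))
    return list(zip(fpr.tolist(), tpr.tolist(), thr.tolist()))


def _aggregate(per_repeat: list[MetricReport]) -> tuple[MetricReport, MetricReport]:
    keys = ["sn", "sp", "precision", "acc", "mcc", "auc"]
    cols = {k: np.array([getattr(r, k) for r in per_repeat], dtype=float) for k in keys}
    mean = {k: float(v.mean()) for k, v in cols.items()}
    sd = {k: float(v.std(ddof=1)) if len(per_repeat) > 1 else 0.0 for k, v in cols.items()}
    return MetricReport(**mean), MetricReport(**sd)


def _fold_scores(
    dataset: WindowDataset,
    y: np.ndarray,
    splits,
    hp: HyperParams,
    protocol: str,
    full_X: np.ndarray | None,
    cost_sensitive: bool = True,
) -> np.ndarray:
    """Out-of-fold decision scores for one pass over the folds."""
    scores = np.empty(len(y), dtype=float)
    windows = dataset.windows
    for train_idx, test_idx in splits:
        if protocol == "paper":
            X_train, X_test = full_X[train_idx], full_X[test_idx]
        else:
            train_ds = WindowDataset(
                windows=[windows[i] for i in train_idx], zeta=dataset.zeta
            )
            fold_model = fit_model(train_ds)
            X_train = encode_windows(train_ds.windows, fold_model)
            X_test = encode_windows([windows[i] for i in test_idx], fold_model)
        if cost_sensitive:
            scheme = class_costs(
                n=len(train_idx), q=int((y[train_idx] == 1).sum()), C=hp.C
            )
        else:
            scheme = class_costs(n=2, q=1, C=hp.C)  # balanced: C+ = C- = C
        model = costsvm.fit(X_train, y[train_idx], params=hp, scheme=scheme)
        scores[test_idx] = model.decision_scores(X_test)
    return scores


def repeated_cv(
    dataset: WindowDataset,
    config: CVConfig,
    hyperparams: HyperParams | None = None,
    C_grid: Sequence[float] | None = None,
    gamma_grid: Sequence[float] | None = None,
    cost_sensitive: bool = True,
) -> CVResult:
    """Repeated stratified k-fold cross-validation with pooled metrics.

    Each repeat draws fresh folds (seeded ``config.seed + repeat``),
    scores every sample exactly once out-of-fold, pools the decision
    scores, and computes the confusion metrics at threshold 0 plus the
    pooled AUC.  Hyperparameters come from, in order of precedence,
    ``config.per_repeat_hyperparams``, the fixed *hyperparams*, or an
    AUC-maximising grid search run inside the repeat.  Setting
    ``cost_sensitive=False`` trains plain unweighted SVMs (both class
    penalties equal to C), which is useful for quantifying what the
    imbalance correction buys.
    """
    y = np.array([1 if w.label == POSITIVE else -1 for w in dataset.windows])
    if (y == 1).sum() == 0 or (y == -1).sum() == 0:
        raise EvaluationError("cross-validation needs both classes")
    if (y == 1).sum() < config.folds:
        warnings.warn(
            f"only {(y == 1).sum()} positives for {config.folds} folds; "
            "some folds will hold a single positive"
        )

    full_X = None
    if config.protocol == "paper":
        full_model = fit_model(dataset)
        full_X = encode_windows(dataset.windows, full_model)

    per_repeat: list[MetricReport] = []
    chosen: list[HyperParams] = []
    for r in range(config.repeats):
        skf = StratifiedKFold(
            n_splits=config.folds, shuffle=True, random_state=config.seed + r
        )
        splits = list(skf.split(np.zeros(len(y)), y))
        if config.per_repeat_hyperparams is not None:
            hp = config.per_repeat_hyperparams[r]
        elif hyperparams is not None:
            hp = hyperparams
        else:
            def pooled_auc(candidate: HyperParams) -> float:
                s = _fold_scores(
                    dataset, y, splits, candidate, config.protocol, full_X,
                    cost_sensitive,
                )
                return roc_auc(y, s)

            hp, _ = costsvm.grid_search(
                pooled_auc,
                C_grid or costsvm.DEFAULT_C_GRID,
                gamma_grid or costsvm.DEFAULT_GAMMA_GRID,
            )
        chosen.append(hp)
        scores = _fold_scores(
            dataset, y, splits, hp, config.protocol, full_X, cost_sensitive
        )
        preds = np.where(scores > 0, 1, -1)
        per_repeat.append(metrics(confusion(y, preds), auc=roc_auc(y, scores)))

    mean, sd = _aggregate(per_repeat)
    return CVResult(mean=mean, sd=sd, per_repeat=per_repeat, hyperparams=chosen)


def independent_test(
    benchmark: WindowDataset,
    independent: WindowDataset,
    params: HyperParams | None = None,
) -> tuple[MetricReport, np.ndarray]:
    """Train on the benchmark set and evaluate on held-out proteins.

    The coupling tables and the classifier are both fitted on the full
    benchmark; independent windows are encoded with the benchmark tables.
    Returns the metric report and the decision scores for the independent
    windows.  Overlapping protein ids between the two sets trigger a
    warning naming the offenders.
    """
    params = params or HyperParams()
    overlap = sorted(
        {w.protein_id for w in benchmark.windows}
        & {w.protein_id for w in independent.windows}
    )
    if overlap:
        warnings.warn(
            f"independent set shares {len(overlap)} protein(s) with the "
            f"benchmark: {overlap[:10]}"
        )
    model = fit_model(benchmark)
    X_train = encode_windows(benchmark.windows, model)
    y_train = np.array([1 if w.label == POSITIVE else -1 for w in benchmark.windows])
    scheme = class_costs(n=len(y_train), q=int((y_train == 1).sum()), C=params.C)
    svm = costsvm.fit(X_train, y_train, params=params, scheme=scheme)

    X_test = encode_windows(independent.windows, model)
    y_test = np.array([1 if w.label == POSITIVE else -1 for w in independent.windows])
    scores = svm.decision_scores(X_test)
    preds = np.where(scores > 0, 1, -1)
    auc = roc_auc(y_test, scores) if len(set(y_test.tolist())) == 2 else None
    return metrics(confusion(y_test, preds), auc=auc), scores


# ---------------------------------------------------------------------------
# Report writers

def cv_result_to_dict(result: CVResult) -> dict:
    return {
        "mean": result.mean.to_dict(),
        "sd": result.sd.to_dict(),
        "per_repeat": [r.to_dict() for r in result.per_repeat],
        "hyperparams": [
            {"C": hp.C, "gamma": hp.gamma} for hp in result.hyperparams
        ],
    }


def write_json_report(payload: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def write_tsv_report(reports: dict[str, MetricReport], path: str | Path) -> None:
    """One row per named report, metric columns in a fixed order."""
    keys = ["sn", "sp", "precision", "acc", "mcc", "auc"]
    with open(path, "w") as fh:
        fh.write("name\t" + "\t".join(keys) + "\n")
        for name, rep in reports.items():
            d = rep.to_dict()
            fh.write(
                name
                + "\t"
                + "\t".join(
                    "NA" if d[k] is None else f"{d[k]:.6f}" for k in keys
                )
                + "\n"
            )


def write_roc_points(
    points: Sequence[tuple[float, float, float]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\tthreshold\n")
        for fpr, tpr, thr in points:
            fh.write(f"{fpr:.6f}\t{tpr:.6f}\t{thr:.6g}\n")
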