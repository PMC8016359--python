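"""Cost-sensitive RBF-kernel support vector classification.

With q positive and n - q negative training samples, slack on the two
classes is penalised asymmetrically:

    C+ = C * n / (2 q)          (positive-class penalty)
    C- = C * n / (2 (n - q))    (negative-class penalty)

so that q * C+ = (n - q) * C- = C * n / 2: the two classes carry equal
total misclassification budget regardless of imbalance, and at balance
(n = 2q) both penalties reduce to the base cost C.  The quadratic
program itself is delegated to scikit-learn's SVC; this module owns the
cost scheme, the RBF configuration and the hyperparameter grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Callable, Sequence

import joblib
import numpy as np
from sklearn.svm import SVC

#: Hyperparameter grids scanned during model selection: C = 2^0..2^8,
#: gamma = 2^-1..2^-8.
DEFAULT_C_GRID = tuple(2.0**k for k in range(0, 9))
DEFAULT_GAMMA_GRID = tuple(2.0**-k for k in range(1, 9))

#: Selection used for the final predictor (modal choice across repeats).
DEFAULT_C = 2.0**0
DEFAULT_GAMMA = 2.0**-2


class CostSVMError(ValueError):
    """Raised for degenerate class counts or inconsistent inputs."""


@dataclass(frozen=True)
class CostScheme:
    """Per-class slack penalties derived from the class counts."""

    base_cost: float
    n: int
    q: int

    def __post_init__(self) -> None:
        if self.base_cost <= 0:
            raise CostSVMError(f"base cost must be > 0, got {self.base_cost}")
        if not 0 < self.q < self.n:
            raise CostSVMError(
                f"need 0 < q < n for a two-class cost scheme, got q={self.q}, n={self.n}"
            )

    @property
    def c_plus(self) -> float:
        return self.base_cost * self.n / (2 * self.q)

    @property
    def c_minus(self) -> float:
        return self.base_cost * self.n / (2 * (self.n - self.q))

    def as_fractions(self) -> tuple[Fraction, Fraction]:
        """Exact per-class costs when the base cost is rational."""
        c = Fraction(self.base_cost)
        return c * self.n / (2 * self.q), c * self.n / (2 * (self.n - self.q))


def class_costs(n: int, q: int, C: float = 1.0) -> CostScheme:
    """Build the cost scheme for *n* samples of which *q* are positive."""
    return CostScheme(base_cost=C, n=n, q=q)


@dataclass(frozen=True)
class HyperParams:
    """SVM hyperparameters: soft-margin base cost C and RBF width gamma."""

    C: float = DEFAULT_C
    gamma: float = DEFAULT_GAMMA

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise CostSVMError(f"C and gamma must be > 0, got {self}")


@dataclass
class TrainedModel:
    """A fitted cost-sensitive SVM plus the configuration that produced it."""

    estimator: SVC
    hyperparams: HyperParams
    cost_scheme: CostScheme
    feature_dim: int

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.feature_dim:
            raise CostSVMError(
                f"expected feature matrix with {self.feature_dim} columns, "
                f"got shape {X.shape}"
            )
        return X

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Signed margin distances; higher means more positive-class."""
        return self.estimator.decision_function(self._check(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class labels in {+1, -1}; the threshold is decision score 0."""
        return np.where(self.decision_scores(X) > 0, 1, -1)


def fit(
    X: np.ndarray,
    y: Sequence[int],
    params: HyperParams | None = None,
    scheme: CostScheme | None = None,
) -> TrainedModel:
    """Train the cost-sensitive RBF SVM.

    Labels are +1 (modified site) / -1.  When *scheme* is omitted it is
    derived from the class counts of ``y`` with base cost ``params.C``.
    The per-class penalties are applied exactly: the solver's C is the
    negative-class penalty C- and the positive class carries the weight
    C+/C-.
    """
    params = params or HyperParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) == 0:
        raise CostSVMError(f"bad feature matrix shape {X.shape}")
    if len(X) != len(y):
        raise CostSVMError(f"{len(X)} feature rows but {len(y)} labels")
    if not np.isfinite(X).all():
        raise CostSVMError("feature matrix contains NaN or infinite values")
    if set(np.unique(y)) != {-1, 1}:
        raise CostSVMError(f"labels must contain both +1 and -1, got {set(y)}")
    if scheme is None:
        scheme = class_costs(n=len(y), q=int((y == 1).sum()), C=params.C)
    est = SVC(
        kernel="rbf",
        C=scheme.c_minus,
        gamma=params.gamma,
        class_weight={1: scheme.c_plus / scheme.c_minus, -1: 1.0},
        shrinking=True,
        cache_size=200,
        random_state=0,
    )
    est.fit(X, y)
    return TrainedModel(
        estimator=est,
        hyperparams=params,
        cost_scheme=scheme,
        feature_dim=X.shape[1],
    )


def grid_search(
    evaluate: Callable[[HyperParams], float],
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
) -> tuple[HyperParams, list[tuple[HyperParams, float]]]:
    """Scan the (C, gamma) grid and return the AUC-maximising point.

    *evaluate* maps hyperparameters to a cross-validated AUC (supplied by
    the evaluation layer so the protocol stays in one place).  Ties break
    towards smaller C, then larger gamma — the iteration order below —
    via the strict ``>`` comparison.
    """
    if not C_grid or not gamma_grid:
        raise CostSVMError("hyperparameter grids must be non-empty")
    table: list[tuple[HyperParams, float]] = []
    best: HyperParams | None = None
    best_auc = -np.inf
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid, reverse=True):
            hp = HyperParams(C=C, gamma=gamma)
            auc = evaluate(hp)
            table.append((hp, auc))
            if auc > best_auc:
                best, best_auc = hp, auc
    assert best is not None
    return best, table


def save_model(model: TrainedModel, coupling_model, path: str | Path) -> None:
    """Serialise the classifier together with the coupling tables it needs."""
    joblib.dump({"svm": model, "coupling": coupling_model}, path)


def load_model(path: str | Path):
    """Load a bundle written by :func:`save_model`; returns (svm, coupling)."""
    bundle = joblib.load(path)
    return bundle["svm"], bundle["coupling"]
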