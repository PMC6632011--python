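"""Instance-level classifiers and group-level vote aggregation.

A classifier votes on each of a group's 24 permutation instances; the votes
are averaged into a group score in [0, 1] and thresholded (score >= theta)
into the group prediction.  The threshold is either fixed (0.5) or optimised
on the training sessions over the 25 achievable vote fractions k/24.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import DegenerateTrainingError, LayoutError, ProtocolError
from .groups import N_PERMUTATIONS, GadInstance, GadLayout

#: The 25 achievable group-score values k/24, used as the threshold grid.
THRESHOLD_GRID = tuple(k / N_PERMUTATIONS for k in range(N_PERMUTATIONS + 1))


def fold_seed(session_id: str, experiment_seed: int) -> int:
    """Deterministic per-fold RNG seed from the held-out session id.

    Stable across processes (unlike the builtin ``hash``) and below 2**31.
    """
    digest = hashlib.blake2s(
        f"{session_id}:{experiment_seed}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


# --------------------------------------------------------------------------
# Models
# --------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """A fitted instance-level classifier exposing binary votes."""

    kind: str  # random_forest | svm_baseline | trivial
    n_features: int
    _predict: object = field(repr=False)
    estimator: object = field(default=None, repr=False)

    def predict_votes(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise LayoutError(
                f"expected instances of length {self.n_features}, got {X.shape}"
            )
        votes = np.asarray(self._predict(X)).astype(int)
        return votes


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError("training labels contain a single class")


def train_random_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 100,
    seed: int = 0,
    vote_mode: str = "hard",
) -> TrainedModel:
    """Random forest with sqrt(d) features per split and unlimited depth.

    The instance vote is the majority of the trees' hard predictions
    (``vote_mode="hard"``); ``"proba"`` thresholds the averaged tree
    probabilities at 0.5 instead (sensitivity mode).
    """
    X = np.ascontiguousarray(X, dtype=np.float32)
    y = np.asarray(y).astype(int)
    _check_two_classes(y)
    if n_trees < 1:
        raise DegenerateTrainingError("n_trees must be >= 1")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)

    if vote_mode == "hard":
        def predict(Xt: np.ndarray) -> np.ndarray:
            Xt = np.ascontiguousarray(Xt, dtype=np.float32)
            acc = np.zeros(Xt.shape[0])
            for est in forest.estimators_:
                acc += est.predict(Xt, check_input=False)
            return (acc / len(forest.estimators_) >= 0.5).astype(int)
    elif vote_mode == "proba":
        def predict(Xt: np.ndarray) -> np.ndarray:
            proba = forest.predict_proba(np.asarray(Xt, dtype=np.float32))
            return (proba[:, list(forest.classes_).index(1)] >= 0.5).astype(int)
    else:
        raise ProtocolError(f"unknown vote_mode {vote_mode!r}")

    return TrainedModel("random_forest", X.shape[1], predict, forest)


def train_trivial(train_labels) -> TrainedModel:
    """Constant predictor of the training majority class (tie -> 1)."""
    y = np.asarray(train_labels).astype(int)
    if y.size == 0:
        raise DegenerateTrainingError("trivial baseline needs at least one label")
    majority = 1 if np.mean(y) >= 0.5 else 0

    def predict(Xt: np.ndarray) -> np.ndarray:
        return np.full(np.asarray(Xt).shape[0], majority, dtype=int)

    m = TrainedModel("trivial", -1, predict)
    # the trivial model accepts any instance length
    m.predict_votes = lambda X: predict(np.atleast_2d(X))  # type: ignore[method-assign]
    m.majority = majority  # type: ignore[attr-defined]
    return m


def train_svm_baseline(X: np.ndarray, y: np.ndarray, c: float = 1.0) -> TrainedModel:
    """Linear-kernel SVM with training-fold standardisation (margin methods
    need scaled inputs; the forest does not)."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    _check_two_classes(y)
    pipe = make_pipeline(StandardScaler(), SVC(kernel="linear", C=c))
    pipe.fit(X, y)
    return TrainedModel("svm_baseline", X.shape[1], lambda Xt: pipe.predict(np.asarray(Xt)), pipe)


# --------------------------------------------------------------------------
# Group-level aggregation
# --------------------------------------------------------------------------


@dataclass
class GroupPrediction:
    group_id: str
    score: float
    predicted: int
    threshold: float
    label: int | None = None


def score_group(
    model: TrainedModel,
    instances: list[GadInstance],
    threshold: float = 0.5,
) -> GroupPrediction:
    """Mean of the 24 instance votes, thresholded with score >= theta."""
    if len(instances) != N_PERMUTATIONS:
        raise ProtocolError(
            f"a group must contribute exactly {N_PERMUTATIONS} instances, "
            f"got {len(instances)}"
        )
    gids = {i.group_id for i in instances}
    if len(gids) != 1:
        raise ProtocolError(f"instances from multiple groups: {sorted(gids)}")
    X = np.stack([i.values for i in instances])
    score = float(np.mean(model.predict_votes(X)))
    return GroupPrediction(
        group_id=instances[0].group_id,
        score=score,
        predicted=int(score >= threshold),
        threshold=threshold,
        label=instances[0].label,
    )


def group_scores_from_votes(votes: np.ndarray, group_index: np.ndarray) -> np.ndarray:
    """Mean vote per group for a stacked instance matrix; ``group_index``
    assigns each instance row to a group (0..G-1)."""
    votes = np.asarray(votes, dtype=float)
    n_groups = int(group_index.max()) + 1
    sums = np.bincount(group_index, weights=votes, minlength=n_groups)
    counts = np.bincount(group_index, minlength=n_groups)
    if np.any(counts != N_PERMUTATIONS):
        raise ProtocolError("every group must contribute exactly 24 instances")
    return sums / counts


# --------------------------------------------------------------------------
# Threshold optimisation (grid logic)
# --------------------------------------------------------------------------


@dataclass
class ThresholdResult:
    grid: tuple[float, ...]
    mean_accuracies: np.ndarray
    chosen: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.grid, "mean_accuracy": self.mean_accuracies})


def choose_threshold(fold_scores: list[tuple[np.ndarray, np.ndarray]]) -> ThresholdResult:
    """Exhaustive grid search over k/24 on inner-fold group scores.

    ``fold_scores`` holds per inner fold the (scores, labels) of its held-out
    groups.  The chosen threshold maximises the mean per-fold accuracy; ties
    are broken by minimal |theta - 0.5|, then by the smaller theta.
    """
    if not fold_scores:
        raise ProtocolError("threshold optimisation needs at least one inner fold")
    grid = np.asarray(THRESHOLD_GRID)
    accs = np.empty((len(fold_scores), len(grid)))
    for i, (scores, labels) in enumerate(fold_scores):
        scores = np.asarray(scores, dtype=float)[:, None]
        labels = np.asarray(labels).astype(int)[:, None]
        pred = (scores >= grid[None, :]).astype(int)
        accs[i] = np.mean(pred == labels, axis=0)
    mean_accs = accs.mean(axis=0)
    best = mean_accs.max()
    ties = np.flatnonzero(mean_accs >= best - 1e-12)
    order = sorted(ties, key=lambda j: (abs(grid[j] - 0.5), grid[j]))
    return ThresholdResult(THRESHOLD_GRID, mean_accs, float(grid[order[0]]))


# --------------------------------------------------------------------------
# Feature importance
# --------------------------------------------------------------------------


def aggregate_importance(model: TrainedModel, layout: GadLayout) -> pd.DataFrame:
    """Per base channel, the summed impurity importance over its 48 statistics
    x 4 participant slots (x parts), sorted descending.  Total importance is
    conserved: the column sums to the sum of the per-dimension importances."""
    if model.kind != "random_forest":
        raise ProtocolError("importances require a random forest model")
    imp = model.estimator.feature_importances_
    if imp.shape[0] != layout.dimension:
        raise LayoutError(
            f"model has {imp.shape[0]} dimensions but layout expects {layout.dimension}"
        )
    chan = layout.channel_of_dim()
    sums = np.bincount(chan, weights=imp, minlength=len(layout.channel_names))
    df = pd.DataFrame({"channel": layout.channel_names, "importance": sums})
    return df.sort_values("importance", ascending=False, ignore_index=True)
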