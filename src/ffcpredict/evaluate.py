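"""Evaluation protocols: leave-one-session-out CV, nested threshold tuning,
the temporal-split experiment catalogue, ablations and model comparisons.

Sessions are the cross-validation unit because subjects can recur across
groups within a session but never across sessions; holding out whole sessions
therefore guarantees subject-independent test folds.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .descriptors import WHOLE_VIDEO, SegmentSpec, compute_fad_part
from .errors import ConfigurationError, ProtocolError
from .groups import (
    N_PERMUTATIONS,
    PERMUTATIONS,
    GadLayout,
    gad_dimension,
)
from .io import Dataset, FeatureSetSpec, feature_set
from .models import (
    GroupPrediction,
    ThresholdResult,
    choose_threshold,
    fold_seed,
    group_scores_from_votes,
    train_random_forest,
    train_svm_baseline,
    train_trivial,
)

# --------------------------------------------------------------------------
# Configuration and results
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentConfig:
    """One model configuration of the pipeline."""

    feature_set: str = "FF4"
    segment: SegmentSpec = WHOLE_VIDEO
    model: str = "random_forest"  # random_forest | svm_baseline | trivial
    n_trees: int = 100
    threshold: float = 0.5
    threshold_mode: str = "fixed"  # fixed | optimal
    vote_mode: str = "hard"
    seed: int = 0
    weight_folds_by_groups: bool = False


@dataclass
class FoldResult:
    held_out_session: str
    predictions: list[GroupPrediction]
    threshold: float
    threshold_search: ThresholdResult | None = None

    @property
    def n_groups(self) -> int:
        return len(self.predictions)

    @property
    def accuracy(self) -> float:
        return float(np.mean([p.predicted == p.label for p in self.predictions]))


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    folds: list[FoldResult] = field(default_factory=list)

    @property
    def fold_accuracies(self) -> np.ndarray:
        return np.array([f.accuracy for f in self.folds])

    @property
    def mean_accuracy(self) -> float:
        accs = self.fold_accuracies
        if self.config.weight_folds_by_groups:
            w = np.array([f.n_groups for f in self.folds], dtype=float)
            return float(np.average(accs, weights=w))
        return float(accs.mean())

    @property
    def thresholds(self) -> list[float]:
        return [f.threshold for f in self.folds]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "session": [f.held_out_session for f in self.folds],
                "n_groups": [f.n_groups for f in self.folds],
                "threshold": self.thresholds,
                "accuracy": self.fold_accuracies,
            }
        )


# --------------------------------------------------------------------------
# Design matrices with FAD caching
# --------------------------------------------------------------------------


class FadCache:
    """Memoises per-part FAD values keyed by (group, slot, feature set, k, part)
    so split experiments recompute nothing across catalogue entries."""

    def __init__(self) -> None:
        self._store: dict[tuple, np.ndarray] = {}

    def get(self, group, slot: int, spec: FeatureSetSpec, divisions: int, part: int) -> np.ndarray:
        key = (group.group_id, slot, spec.name, divisions, part)
        if key not in self._store:
            fad = compute_fad_part(group.participants[slot], spec, divisions, part)
            self._store[key] = fad.values
        return self._store[key]


@dataclass
class DesignMatrix:
    """Stacked GAD instances for a whole dataset, with group/session indices."""

    X: np.ndarray  # (24 * n_groups, dim) float32
    instance_labels: np.ndarray
    instance_group: np.ndarray  # group row index per instance
    group_ids: list[str]
    group_labels: np.ndarray
    group_sessions: list[str]
    layout: GadLayout

    @property
    def session_ids(self) -> list[str]:
        seen: list[str] = []
        for s in self.group_sessions:
            if s not in seen:
                seen.append(s)
        return seen

    def rows_of_sessions(self, sessions: set[str]) -> np.ndarray:
        in_sel = np.array([s in sessions for s in self.group_sessions])
        return np.flatnonzero(np.repeat(in_sel, N_PERMUTATIONS))

    def groups_of_session(self, session: str) -> np.ndarray:
        return np.flatnonzero(np.array([s == session for s in self.group_sessions]))


def build_design(
    data: Dataset,
    spec: FeatureSetSpec,
    segment: SegmentSpec = WHOLE_VIDEO,
    cache: FadCache | None = None,
) -> DesignMatrix:
    cache = cache or FadCache()
    dim = gad_dimension(spec, segment)
    n_groups = len(data.groups)
    X = np.empty((n_groups * N_PERMUTATIONS, dim), dtype=np.float32)
    inst_labels = np.empty(n_groups * N_PERMUTATIONS, dtype=int)
    inst_group = np.repeat(np.arange(n_groups), N_PERMUTATIONS)
    group_ids, group_labels, group_sessions = [], [], []
    for gi, group in enumerate(data.groups):
        blocks = [
            np.concatenate(
                [cache.get(group, slot, spec, segment.divisions, p) for p in segment.parts]
            )
            for slot in range(4)
        ]
        base = gi * N_PERMUTATIONS
        for k, perm in enumerate(PERMUTATIONS):
            X[base + k] = np.concatenate([blocks[i] for i in perm])
        inst_labels[base : base + N_PERMUTATIONS] = group.label
        group_ids.append(group.group_id)
        group_labels.append(group.label)
        group_sessions.append(group.session_id)
    layout = GadLayout(spec.name, segment, tuple(spec.selected))
    return DesignMatrix(
        X, inst_labels, inst_group, group_ids, np.array(group_labels), group_sessions, layout
    )


# --------------------------------------------------------------------------
# Fold machinery
# --------------------------------------------------------------------------


def _train_model(design: DesignMatrix, train_rows: np.ndarray, config: ExperimentConfig, seed: int):
    Xtr = design.X[train_rows]
    ytr = design.instance_labels[train_rows]
    if config.model == "random_forest":
        return train_random_forest(Xtr, ytr, config.n_trees, seed, config.vote_mode)
    if config.model == "svm_baseline":
        return train_svm_baseline(Xtr, ytr)
    if config.model == "trivial":
        return train_trivial(ytr)
    raise ConfigurationError(f"unknown model kind {config.model!r}")


def _fold_group_scores(
    design: DesignMatrix,
    train_sessions: set[str],
    test_session: str,
    config: ExperimentConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Train on ``train_sessions``, return (scores, labels, group indices) of
    the held-out session's groups."""
    train_rows = design.rows_of_sessions(train_sessions)
    model = _train_model(design, train_rows, config, fold_seed(test_session, config.seed))
    test_groups = design.groups_of_session(test_session)
    test_rows = design.rows_of_sessions({test_session})
    votes = model.predict_votes(design.X[test_rows])
    local_group = np.repeat(np.arange(len(test_groups)), N_PERMUTATIONS)
    scores = group_scores_from_votes(votes, local_group)
    return scores, design.group_labels[test_groups], test_groups


def _fold_result(
    design: DesignMatrix,
    scores: np.ndarray,
    test_groups: np.ndarray,
    test_session: str,
    threshold: float,
    search: ThresholdResult | None = None,
) -> FoldResult:
    preds = [
        GroupPrediction(
            group_id=design.group_ids[g],
            score=float(s),
            predicted=int(s >= threshold),
            threshold=threshold,
            label=int(design.group_labels[g]),
        )
        for g, s in zip(test_groups, scores)
    ]
    return FoldResult(test_session, preds, threshold, search)


def _check_sessions(design: DesignMatrix, minimum: int) -> list[str]:
    sessions = design.session_ids
    if len(sessions) < minimum:
        raise ProtocolError(f"protocol requires >= {minimum} sessions, got {len(sessions)}")
    for s in sessions:
        if len(design.groups_of_session(s)) == 0:
            raise ProtocolError(f"session {s!r} has no groups")
    return sessions


# --------------------------------------------------------------------------
# Cross-validation protocols
# --------------------------------------------------------------------------


def loso_cv(
    data: Dataset,
    config: ExperimentConfig = ExperimentConfig(),
    design: DesignMatrix | None = None,
) -> ExperimentResult:
    """Leave-one-session-out CV with a fixed decision threshold.

    One fold per session: train on all other sessions' instances, score each
    held-out group (mean of its 24 permutation votes), threshold, and report
    the unweighted mean of the per-session accuracies.
    """
    if design is None:
        design = build_design(data, feature_set(config.feature_set), config.segment)
    sessions = _check_sessions(design, 2)
    result = ExperimentResult(config)
    for s in sessions:
        scores, _, test_groups = _fold_group_scores(
            design, set(sessions) - {s}, s, config
        )
        result.folds.append(_fold_result(design, scores, test_groups, s, config.threshold))
    return result


def optimize_threshold(
    design: DesignMatrix,
    train_sessions: list[str],
    config: ExperimentConfig,
) -> ThresholdResult:
    """Inner leave-one-session-out over the training sessions.

    Each inner fold trains one model and scores its held-out session's groups;
    the grid k/24 is evaluated exhaustively on those scores and the threshold
    with the best mean inner accuracy is chosen (ties: nearest 0.5, then
    smaller).
    """
    if len(train_sessions) < 2:
        raise ProtocolError("threshold optimisation requires >= 2 training sessions")
    fold_scores = []
    for s in train_sessions:
        scores, labels, _ = _fold_group_scores(
            design, set(train_sessions) - {s}, s, config
        )
        fold_scores.append((scores, labels))
    return choose_threshold(fold_scores)


def nested_cv(
    data: Dataset,
    config: ExperimentConfig = ExperimentConfig(),
    design: DesignMatrix | None = None,
) -> ExperimentResult:
    """Nested CV: the outer loop estimates accuracy, the inner loop picks the
    decision threshold on the outer-training sessions only."""
    if design is None:
        design = build_design(data, feature_set(config.feature_set), config.segment)
    sessions = _check_sessions(design, 3)
    result = ExperimentResult(config)
    for s in sessions:
        train_sessions = [t for t in sessions if t != s]
        search = optimize_threshold(design, train_sessions, config)
        scores, _, test_groups = _fold_group_scores(design, set(train_sessions), s, config)
        result.folds.append(
            _fold_result(design, scores, test_groups, s, search.chosen, search)
        )
    return result


def run_cv(data: Dataset, config: ExperimentConfig, design: DesignMatrix | None = None) -> ExperimentResult:
    if config.threshold_mode == "optimal":
        return nested_cv(data, config, design)
    if config.threshold_mode == "fixed":
        return loso_cv(data, config, design)
    raise ConfigurationError(f"unknown threshold_mode {config.threshold_mode!r}")


def audit_no_leakage(data: Dataset) -> None:
    """Assert that no participant id spans two sessions (LOSO soundness)."""
    seen: dict[str, str] = {}
    for g in data.groups:
        for p in g.participants:
            prev = seen.setdefault(p.participant_id, g.session_id)
            if prev != g.session_id:
                raise ProtocolError(
                    f"participant {p.participant_id!r} leaks across sessions "
                    f"{prev!r} and {g.session_id!r}"
                )


# --------------------------------------------------------------------------
# Split catalogue
# --------------------------------------------------------------------------

CATEGORIES = ("combined", "beginning", "end")


@dataclass(frozen=True)
class CatalogueEntry:
    category: str
    segment: SegmentSpec

    def __str__(self) -> str:
        return f"{self.category}:{self.segment}"


@dataclass(frozen=True)
class SplitCatalogue:
    """The frozen catalogue of temporal-split models (3 categories x 11)."""

    entries: tuple[CatalogueEntry, ...]

    def by_category(self, category: str) -> list[CatalogueEntry]:
        return [e for e in self.entries if e.category == category]

    def __len__(self) -> int:
        return len(self.entries)


def base_splits() -> list[SegmentSpec]:
    """The 12 single-part splits: thirds, quarters and fifths (3+4+5)."""
    return [SegmentSpec(k, (p,)) for k in (3, 4, 5) for p in range(1, k + 1)]


def load_split_catalogue() -> SplitCatalogue:
    path = importlib.resources.files("ffcpredict.data") / "split_catalogue.csv"
    with importlib.resources.as_file(path) as p:
        df = pd.read_csv(p)
    entries = tuple(
        CatalogueEntry(
            str(r.category),
            SegmentSpec(int(r.divisions), tuple(int(x) for x in str(r.parts).split("&"))),
        )
        for r in df.itertuples()
    )
    cat = SplitCatalogue(entries)
    for c in CATEGORIES:
        if len(cat.by_category(c)) != 11:
            raise ConfigurationError(f"catalogue category {c!r} must have 11 entries")
    return cat


def run_split_experiments(
    data: Dataset,
    catalogue: SplitCatalogue | None = None,
    config: ExperimentConfig = ExperimentConfig(),
    include_base_splits: bool = False,
    cache: FadCache | None = None,
) -> pd.DataFrame:
    """One cross-validated experiment per catalogue entry (optionally plus the
    12 base splits), sharing one FAD cache across entries.

    Returns a table with category, segment, per-entry mean accuracy and the
    per-fold accuracies (as a list column for downstream statistics).
    """
    catalogue = catalogue or load_split_catalogue()
    cache = cache or FadCache()
    spec = feature_set(config.feature_set)
    rows = []
    jobs: list[tuple[str, SegmentSpec]] = [(e.category, e.segment) for e in catalogue.entries]
    if include_base_splits:
        jobs += [("base", s) for s in base_splits()]
    for category, segment in jobs:
        design = build_design(data, spec, segment, cache)
        res = run_cv(data, replace(config, segment=segment), design)
        rows.append(
            {
                "category": category,
                "segment": str(segment),
                "mean_accuracy": res.mean_accuracy,
                "fold_accuracies": list(res.fold_accuracies),
            }
        )
    return pd.DataFrame(rows)


def category_summary(results: pd.DataFrame, pool_folds: bool = False) -> pd.DataFrame:
    """Boxplot statistics per category, either over model means (default) or
    pooling every fold accuracy of the category's models."""
    rows = []
    for cat, sub in results.groupby("category", sort=False):
        if pool_folds:
            vals = np.concatenate([np.asarray(a) for a in sub["fold_accuracies"]])
        else:
            vals = sub["mean_accuracy"].to_numpy()
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {
                "category": cat,
                "n_models": len(sub),
                "mean": vals.mean(),
                "min": vals.min(),
                "q1": q1,
                "median": med,
                "q3": q3,
                "max": vals.max(),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Model comparison
# --------------------------------------------------------------------------


def compare_models_ranktest(a, b, method: str = "wilcoxon") -> float:
    """Two-sided rank test on paired per-fold accuracies.

    Default is the paired Wilcoxon signed-rank test with zero differences
    dropped (exact null distribution where scipy supports it); ``method=
    "mannwhitney"`` runs the unpaired rank-sum test instead.  Comparisons
    against the uninformed guess use a constant vector of 0.5.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ProtocolError("fold-accuracy vectors must be 1-D and equally long")
    if len(a) < 5:
        raise ProtocolError("rank tests need at least 5 paired folds")
    if method == "mannwhitney":
        return float(_stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    if method != "wilcoxon":
        raise ConfigurationError(f"unknown rank-test method {method!r}")
    if np.all(a == b):
        return 1.0
    res = _stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return float(res.pvalue)


def uninformed_guess(n_folds: int) -> np.ndarray:
    """The chance-level reference: 50% accuracy in every fold."""
    return np.full(n_folds, 0.5)


# --------------------------------------------------------------------------
# Ablation sequence
# --------------------------------------------------------------------------


def run_ablation(
    data: Dataset,
    feature_set_name: str = "FF4",
    small_trees: int = 30,
    large_trees: int = 5000,
    seed: int = 0,
    catalogue: SplitCatalogue | None = None,
) -> pd.DataFrame:
    """The five-step ablation: whole-video small forest; large forest;
    + optimised threshold; combined-split models; end-split models.

    Rows 4 and 5 report the mean over their category's 11 models.
    """
    catalogue = catalogue or load_split_catalogue()
    cache = FadCache()
    base = ExperimentConfig(feature_set=feature_set_name, seed=seed)
    rows = []

    def add(exp, all_frames, trees, optimal, category, acc):
        rows.append(
            {
                "experiment": exp,
                "all_frames": all_frames,
                "n_trees": trees,
                "optimal_threshold": optimal,
                "split_category": category,
                "mean_accuracy": acc,
            }
        )

    spec = feature_set(feature_set_name)
    whole = build_design(data, spec, WHOLE_VIDEO, cache)
    cfg1 = replace(base, n_trees=small_trees)
    add(1, True, small_trees, False, None, loso_cv(data, cfg1, whole).mean_accuracy)
    cfg2 = replace(base, n_trees=large_trees)
    add(2, True, large_trees, False, None, loso_cv(data, cfg2, whole).mean_accuracy)
    cfg3 = replace(cfg2, threshold_mode="optimal")
    add(3, True, large_trees, True, None, nested_cv(data, cfg3, whole).mean_accuracy)
    for exp, category in ((4, "combined"), (5, "end")):
        sub = SplitCatalogue(tuple(catalogue.by_category(category)))
        res = run_split_experiments(data, sub, cfg3, cache=cache)
        add(exp, False, large_trees, True, category, res["mean_accuracy"].mean())
    return pd.DataFrame(rows)
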