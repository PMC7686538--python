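"""Binary population classification with serial importance-ranked selection.

A random forest (500 trees by default) is fit on all features to obtain
impurity-based importances; features are then ranked and re-evaluated
serially — top-1, top-2, ... top-K — each by stratified 10-fold
cross-validated accuracy. The reported model is the smallest feature subset
whose accuracy is within a parsimony tolerance (default 0.01, absolute) of
the best point on the curve.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.utils.validation import check_is_fitted

from .genotype_io import GenotypeBlock, PopulationPanel
from .scores import build_feature_table


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from one pipeline seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def select_optimal(curve, tolerance: float = 0.01) -> int:
    """Smallest k whose accuracy is within ``tolerance`` of the curve maximum.

    ``curve[i]`` is the accuracy of the top-(i+1) model; returns k (1-based).
    """
    curve = np.asarray(curve, dtype=float)
    if curve.size == 0:
        raise ValueError("empty accuracy curve")
    return int(np.argmax(curve >= curve.max() - tolerance)) + 1


class SerialRandomForestSelector(ClassifierMixin, BaseEstimator):
    """Random-forest classifier with serial importance-ranked selection.

    Fitted attributes
    -----------------
    importances_ : ndarray, full-model impurity importances (sum to 1)
    ranking_ : ndarray of column indices, best first (ties broken by name)
    cv_curve_ : ndarray, cv_curve_[k-1] = CV accuracy of the top-k model
    optimal_k_, optimal_features_, accuracy_ : the parsimony-selected model
    """

    def __init__(
        self,
        n_trees: int = 500,
        n_folds: int = 10,
        tolerance: float = 0.01,
        random_state: int | None = None,
    ):
        self.n_trees = n_trees
        self.n_folds = n_folds
        self.tolerance = tolerance
        self.random_state = random_state

    def _forest(self, seed):
        return RandomForestClassifier(
            n_estimators=self.n_trees, random_state=seed, n_jobs=1
        )

    def _cv(self, X, y, seed):
        cv = StratifiedKFold(self.n_folds, shuffle=True, random_state=seed)
        return float(
            cross_val_score(self._forest(seed), X, y, cv=cv, n_jobs=1).mean()
        )

    def fit(self, X, y):
        names = (
            list(X.columns)
            if isinstance(X, pd.DataFrame)
            else [f"f{i}" for i in range(np.asarray(X).shape[1])]
        )
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"exactly two classes required, got {len(self.classes_)}"
            )
        counts = [int((y == c).sum()) for c in self.classes_]
        if min(counts) < self.n_folds:
            raise ValueError(
                f"each class needs >= {self.n_folds} subjects for "
                f"{self.n_folds}-fold stratified CV, got {counts}"
            )
        seed = 0 if self.random_state is None else int(self.random_state)
        forest_seed, fold_seed = _spawn_seeds(seed, 2)

        full = self._forest(forest_seed).fit(X, y)
        self.importances_ = full.feature_importances_
        self.feature_names_in_ = np.asarray(names, dtype=object)
        # rank by importance, lexicographic name tie-break for determinism
        self.ranking_ = np.array(
            sorted(
                range(X.shape[1]),
                key=lambda i: (-self.importances_[i], names[i]),
            )
        )
        curve = []
        for k in range(1, X.shape[1] + 1):
            cols = self.ranking_[:k]
            curve.append(self._cv(X[:, cols], y, fold_seed))
        self.cv_curve_ = np.array(curve)
        self.optimal_k_ = select_optimal(self.cv_curve_, self.tolerance)
        self.optimal_indices_ = self.ranking_[: self.optimal_k_]
        self.optimal_features_ = [names[i] for i in self.optimal_indices_]
        self.accuracy_ = float(self.cv_curve_[self.optimal_k_ - 1])
        self.estimator_ = self._forest(forest_seed).fit(
            X[:, self.optimal_indices_], y
        )
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        X = np.asarray(X, dtype=float)
        return self.estimator_.predict(X[:, self.optimal_indices_])


# ---------------------------------------------------------------------------
# functional surface


def cv_accuracy(
    features,
    labels,
    n_trees: int = 500,
    n_folds: int = 10,
    random_state: int | None = None,
) -> tuple[float, pd.Series]:
    """Mean stratified CV accuracy plus full-fit importances (sum to 1)."""
    names = (
        list(features.columns)
        if isinstance(features, pd.DataFrame)
        else [f"f{i}" for i in range(np.asarray(features).shape[1])]
    )
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ValueError("exactly two classes required")
    seed = 0 if random_state is None else int(random_state)
    forest_seed, fold_seed = _spawn_seeds(seed, 2)
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=forest_seed, n_jobs=1
    )
    cv = StratifiedKFold(n_folds, shuffle=True, random_state=fold_seed)
    acc = float(cross_val_score(forest, X, y, cv=cv, n_jobs=1).mean())
    imp = forest.fit(X, y).feature_importances_
    return acc, pd.Series(imp, index=names)


def serial_selection(
    features,
    labels,
    n_trees: int = 500,
    n_folds: int = 10,
    random_state: int | None = None,
) -> np.ndarray:
    """Accuracy curve over top-k feature subsets, k = 1..K."""
    sel = SerialRandomForestSelector(
        n_trees=n_trees, n_folds=n_folds, random_state=random_state
    ).fit(features, labels)
    return sel.cv_curve_


@dataclass
class ExperimentResult:
    """One (reference, target, mode) classification experiment."""

    ref_pop: str
    target_pop: str
    mode: str
    seed: int
    cv_curve: list[float]
    importances: dict[str, float]
    ranked_features: list[str]
    optimal_k: int
    optimal_features: list[str]
    accuracy: float
    n_trees: int = 500
    n_folds: int = 10
    tolerance: float = 0.01
    extras: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "ExperimentResult":
        return cls(**json.loads(text))

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.ref_pop, self.target_pop, self.mode)


def run_experiment(
    blocks: dict[str, GenotypeBlock],
    panel: PopulationPanel,
    ref_pop: str,
    target_pop: str,
    mode: str,
    seed: int = 0,
    n_trees: int = 500,
    n_folds: int = 10,
    tolerance: float = 0.01,
) -> ExperimentResult:
    """Score with ``ref_pop`` as reference, classify ``ref_pop`` vs ``target_pop``.

    Swapping reference and target changes the feature encoding, so the result
    is asymmetric in general.
    """
    if ref_pop == target_pop:
        raise ValueError("reference and target populations must differ")
    table = build_feature_table(blocks, panel, ref_pop, mode)
    labels = panel.labels(table.index)
    keep = np.isin(labels, [ref_pop, target_pop])
    table, labels = table.loc[keep], labels[keep]
    sel = SerialRandomForestSelector(
        n_trees=n_trees,
        n_folds=n_folds,
        tolerance=tolerance,
        random_state=seed,
    ).fit(table, labels)
    names = list(table.columns)
    return ExperimentResult(
        ref_pop=ref_pop,
        target_pop=target_pop,
        mode=mode,
        seed=seed,
        cv_curve=[float(v) for v in sel.cv_curve_],
        importances={n: float(v) for n, v in zip(names, sel.importances_)},
        ranked_features=[names[i] for i in sel.ranking_],
        optimal_k=sel.optimal_k_,
        optimal_features=list(sel.optimal_features_),
        accuracy=sel.accuracy_,
        n_trees=n_trees,
        n_folds=n_folds,
        tolerance=tolerance,
    )


def run_experiment_set(
    blocks: dict[str, GenotypeBlock],
    panel: PopulationPanel,
    populations: list[str],
    mode: str,
    seed: int = 0,
    **kwargs,
) -> dict[tuple[str, str], ExperimentResult]:
    """All ordered (reference, target) experiments for one mode.

    Three populations yield 6 results (3 pairs x 2 orientations), each with
    its own derived seed.
    """
    pairs = [
        (a, b) for a in populations for b in populations if a != b
    ]
    seeds = _spawn_seeds(seed, len(pairs))
    return {
        (a, b): run_experiment(blocks, panel, a, b, mode, seed=s, **kwargs)
        for (a, b), s in zip(pairs, seeds)
    }
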