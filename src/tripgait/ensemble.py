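"""Bagged decision-tree ensembles and importance-based backward elimination.

The classifier throughout is a bagged ensemble of Gini decision trees
(bootstrap resamples, all features available at every split), with a
minimum leaf size of 5 and two tuned hyperparameters: the number of
bagged trees and the maximum number of splits per tree.  Hyperparameters
are tuned by seeded random search over log-spaced grids scored by inner
3-fold cross-validated log-loss.

Backward elimination starts from the ReliefF-selected subset, repeatedly
training an ensemble and dropping the feature with the lowest impurity
importance, yielding one nested model per subset size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from .relieff import split_features_labels

MIN_LEAF_SIZE = 5
_SEARCH_CYCLES = (10, 500)       # log-spaced range for number of trees


@dataclass(frozen=True)
class EnsembleHyperparams:
    """Tunable ensemble settings: tree count, split cap, leaf size."""

    n_learning_cycles: int = 200
    max_num_splits: int | None = None   # None -> n_train - 1 at fit time
    min_leaf_size: int = MIN_LEAF_SIZE

    def __post_init__(self) -> None:
        if self.n_learning_cycles < 1 or self.min_leaf_size < 1:
            raise ValueError("hyperparameters must be >= 1")
        if self.max_num_splits is not None and self.max_num_splits < 1:
            raise ValueError("max_num_splits must be >= 1")


@dataclass
class BaggedTreeEnsemble:
    """A fitted bagged-tree ensemble restricted to a named feature subset.

    Posteriors are the across-tree mean of leaf class frequencies and
    always sum to 1 per row.
    """

    features: list[str]
    hyperparams: EnsembleHyperparams
    seed: int
    model: RandomForestClassifier = field(repr=False)

    @property
    def classes(self) -> np.ndarray:
        return self.model.classes_

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        return self.model.predict_proba(table[self.features].to_numpy(dtype=float))

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.model.predict(table[self.features].to_numpy(dtype=float))


def train_bagged_ensemble(train: pd.DataFrame, features: list[str],
                          hp: EnsembleHyperparams, seed: int) -> BaggedTreeEnsemble:
    """Fit a bagged Gini-tree ensemble on the given feature subset.

    Each of the ``n_learning_cycles`` trees is grown on a bootstrap
    resample (n draws with replacement) with every feature available at
    every split, capped at ``max_num_splits`` splits and
    ``min_leaf_size`` observations per leaf.  Deterministic given seed.
    """
    X, y, features = split_features_labels(train, features)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    max_splits = hp.max_num_splits if hp.max_num_splits is not None else len(y) - 1
    rf = RandomForestClassifier(
        n_estimators=hp.n_learning_cycles,
        criterion="gini",
        max_features=None,            # plain bagging: all features per split
        min_samples_leaf=hp.min_leaf_size,
        max_leaf_nodes=max_splits + 1,  # a tree with s splits has s+1 leaves
        bootstrap=True,
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    rf.fit(X, y)
    return BaggedTreeEnsemble(features=features, hyperparams=hp, seed=seed, model=rf)


def predictor_importance(model: BaggedTreeEnsemble) -> pd.Series:
    """Impurity-based importance per feature, normalised to sum 1.

    Gini impurity decrease is attributed to the splitting feature,
    accumulated over splits, averaged across trees; features never used
    in a split score 0.  If no tree made any split, all scores are 0.
    """
    imp = model.model.feature_importances_
    return pd.Series(imp, index=model.features)


def tune_hyperparams(train: pd.DataFrame, features: list[str], budget: int = 30,
                     seed: int = 0, n_inner_folds: int = 3) -> EnsembleHyperparams:
    """Seeded random search over (n_learning_cycles, max_num_splits).

    Draws are log-uniform over [10, 500] trees and [1, n-1] splits;
    each candidate is scored by inner stratified k-fold log-loss with
    ``min_leaf_size`` fixed at 5.  Falls back to documented defaults
    (200 cycles, n-1 splits) if no candidate can be fitted.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    X, y, features = split_features_labels(train, features)
    n = len(y)
    rng = np.random.default_rng(seed)
    lo_c, hi_c = np.log(_SEARCH_CYCLES[0]), np.log(_SEARCH_CYCLES[1])
    hi_s = np.log(max(n - 1, 1))
    skf = StratifiedKFold(n_splits=n_inner_folds, shuffle=True,
                          random_state=int(seed) % (2**31))
    classes = np.unique(y)

    best: tuple[float, EnsembleHyperparams] | None = None
    for _ in range(budget):
        cycles = int(round(np.exp(rng.uniform(lo_c, hi_c))))
        splits = int(round(np.exp(rng.uniform(0.0, hi_s))))
        hp = EnsembleHyperparams(n_learning_cycles=cycles,
                                 max_num_splits=max(splits, 1))
        try:
            losses = []
            for tr_idx, va_idx in skf.split(X, y):
                sub = train.iloc[tr_idx]
                fit = train_bagged_ensemble(sub, features, hp, seed=seed)
                proba = fit.predict_proba(train.iloc[va_idx])
                losses.append(log_loss(y[va_idx], proba, labels=list(fit.classes)))
            score = float(np.mean(losses))
        except ValueError:
            continue
        if best is None or score < best[0]:
            best = (score, hp)
    if best is None:
        warnings.warn(
            "hyperparameter search produced no valid fit; "
            "falling back to defaults (200 cycles, n-1 splits)",
            stacklevel=2,
        )
        return EnsembleHyperparams(n_learning_cycles=200, max_num_splits=n - 1)
    _ = classes
    return best[1]


@dataclass
class NestedModelSeries:
    """Nested feature subsets S_p ⊃ ... ⊃ S_1 with their trained ensembles.

    ``subsets[k]`` holds the k-feature subset (in ReliefF order);
    ``eliminations`` records, largest subset first, which feature was
    dropped at each step and its importance at the time.
    """

    subsets: dict[int, list[str]]
    eliminations: list[tuple[str, float]]
    models: dict[int, BaggedTreeEnsemble]
    hyperparams: dict[int, EnsembleHyperparams]

    def __post_init__(self) -> None:
        sizes = sorted(self.subsets)
        if sizes != list(range(1, max(sizes) + 1)):
            raise ValueError("subset sizes must be exactly 1..p")
        for k in sizes[:-1]:
            if not set(self.subsets[k]) < set(self.subsets[k + 1]):
                raise ValueError(f"subset of size {k} not nested in size {k + 1}")

    @property
    def sizes(self) -> list[int]:
        return sorted(self.subsets, reverse=True)

    def elimination_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.eliminations, columns=["dropped_feature", "importance"])


def build_nested_models(table: pd.DataFrame, selected: list[str],
                        hp_budget: int = 30, seed: int = 0,
                        tune: bool | str = "once") -> NestedModelSeries:
    """Backward-eliminate from the selected subset, one feature at a time.

    The feature with the lowest impurity importance is dropped at every
    step, ties going to the feature ranked lower in the incoming
    (ReliefF) order; this yields len(selected) nested models of sizes
    p, p-1, ..., 1.  ``tune`` controls the hyperparameter search during
    elimination: "once" (default) searches on the full starting subset
    and reuses the result — the elimination only consumes importance
    rankings, which are insensitive to the exact tree count — while
    "per_subset" re-searches at every size and False skips tuning.
    """
    current = list(selected)
    if not current:
        raise ValueError("selected feature list is empty")
    if tune is True:
        tune = "per_subset"
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * len(current))]
    subsets: dict[int, list[str]] = {}
    models: dict[int, BaggedTreeEnsemble] = {}
    hps: dict[int, EnsembleHyperparams] = {}
    eliminations: list[tuple[str, float]] = []
    shared_hp = (tune_hyperparams(table, current, budget=hp_budget,
                                  seed=child_seeds[0])
                 if tune == "once" else EnsembleHyperparams())
    step = 0
    while current:
        k = len(current)
        if tune == "per_subset":
            hp = tune_hyperparams(table, current, budget=hp_budget,
                                  seed=child_seeds[step])
        else:
            hp = shared_hp
        model = train_bagged_ensemble(table, current, hp, seed=child_seeds[step + 1])
        subsets[k] = list(current)
        models[k] = model
        hps[k] = hp
        if k > 1:
            imp = predictor_importance(model)
            worst = imp.min()
            # tie-break: drop the tied feature ranked lower (later) in the
            # incoming order, i.e. the last tied one in `current`
            tied = [f for f in current if imp[f] == worst]
            dropped = tied[-1]
            eliminations.append((dropped, float(imp[dropped])))
            current = [f for f in current if f != dropped]
        else:
            current = []
        step += 2
    return NestedModelSeries(subsets=subsets, eliminations=eliminations,
                             models=models, hyperparams=hps)
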