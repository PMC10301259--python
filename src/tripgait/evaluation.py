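"""Repeated stratified cross-validation and ROC-based model evaluation.

Every nested model is assessed over 5-fold stratified cross-validation
repeated 10 times (50 train/test splits).  On each test fold a
one-vs-rest ROC curve is computed per class; the model's AUC for that
split is the macro average over classes present in the fold.  Class
assignment is scored at two operating points: the default cutoff (a 0.5
posterior threshold per class) and the optimal cutoff (the per-class
threshold maximising Youden's J = TPR - FPR on the ROC curve).  In the
default ("honest") mode the optimal cutoffs are estimated on the
training split and applied to the test split; an alternative mode
estimates them on the pooled test scores for comparison with protocols
that do not separate the two.

With a scalar per-class cutoff, multiclass assignment needs a rule: a
row is assigned to the class whose posterior clears its cutoff; when
several (or none) do, the class with the largest margin
(posterior - cutoff) wins, ties going to the earlier class in the class
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .ensemble import (EnsembleHyperparams, NestedModelSeries,
                       train_bagged_ensemble, tune_hyperparams)
from .synthetic import OUTCOME_COLUMN


@dataclass(frozen=True)
class CVScheme:
    """Repeated stratified k-fold settings (default 5 folds x 10 repeats)."""

    n_folds: int = 5
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2 or self.n_repeats < 1:
            raise ValueError("need n_folds >= 2 and n_repeats >= 1")

    @property
    def n_splits(self) -> int:
        return self.n_folds * self.n_repeats


def stratified_folds(table: pd.DataFrame, scheme: CVScheme):
    """Train/test index pairs for every (repeat, fold).

    Returns a list of ``(repeat, fold, train_idx, test_idx)``; within a
    repeat the test folds partition the rows exactly, and per-fold class
    proportions stay within one row of the global proportions.
    Deterministic given the scheme seed.
    """
    y = table[OUTCOME_COLUMN].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    too_small = classes[counts < scheme.n_folds]
    if len(too_small):
        raise ValueError(
            f"class(es) {list(too_small)} have fewer members than "
            f"n_folds={scheme.n_folds}; stratified folds impossible"
        )
    out = []
    for rep in range(scheme.n_repeats):
        skf = StratifiedKFold(n_splits=scheme.n_folds, shuffle=True,
                              random_state=(int(scheme.seed) + rep) % (2**31))
        for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
            out.append((rep, fold, tr, te))
    return out


# ---------------------------------------------------------------------------
# ROC, cutoffs, accuracy
# ---------------------------------------------------------------------------

@dataclass
class ClassROC:
    """One-vs-rest ROC for a single positive class."""

    positive_class: str
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class ROCResult:
    """Per-class one-vs-rest curves plus the macro-averaged AUC.

    Classes absent from the labels have no defined curve; they are
    listed in ``missing_classes`` and excluded from the macro average.
    """

    curves: dict[str, ClassROC]
    macro_auc: float
    missing_classes: list[str] = field(default_factory=list)


def roc_one_vs_rest(scores: np.ndarray, labels: np.ndarray,
                    positive_class: str) -> ClassROC:
    """ROC curve sweeping the unique scores; trapezoidal AUC."""
    y_bin = (np.asarray(labels) == positive_class).astype(int)
    if y_bin.sum() == 0 or y_bin.sum() == len(y_bin):
        raise ValueError(
            f"class {positive_class!r} absent (or alone) in labels; ROC undefined"
        )
    fpr, tpr, thr = _sk_roc_curve(y_bin, scores)
    auc = float(roc_auc_score(y_bin, scores))
    return ClassROC(positive_class=positive_class, thresholds=thr,
                    fpr=fpr, tpr=tpr, auc=auc)


def roc_multiclass(posteriors: np.ndarray, labels: np.ndarray,
                   class_order: list[str]) -> ROCResult:
    """One-vs-rest ROC per class; macro AUC over classes present."""
    curves: dict[str, ClassROC] = {}
    missing: list[str] = []
    for j, cls in enumerate(class_order):
        try:
            curves[cls] = roc_one_vs_rest(posteriors[:, j], labels, cls)
        except ValueError:
            missing.append(cls)
    if not curves:
        raise ValueError("no class has a defined ROC curve")
    macro = float(np.mean([c.auc for c in curves.values()]))
    return ROCResult(curves=curves, macro_auc=macro, missing_classes=missing)


def optimal_cutoff(curve: ClassROC) -> float:
    """Threshold maximising Youden's J = TPR - FPR; ties -> lower threshold.

    The lower threshold is preferred at a tie because it keeps the
    higher sensitivity.
    """
    j = curve.tpr - curve.fpr
    best = np.max(j)
    candidates = curve.thresholds[j == best]
    # roc_curve pads the first threshold above the score range; clip to 1
    return float(min(1.0, np.min(candidates)))


def classify_at_cutoff(posteriors: np.ndarray, cutoffs: np.ndarray,
                       class_order: list[str]) -> np.ndarray:
    """Assign classes by per-class threshold exceedance with a margin rule.

    A class whose posterior meets its cutoff claims the row; with
    several (or no) claimants the largest margin posterior - cutoff
    wins, the earlier class in ``class_order`` breaking exact ties.
    """
    posteriors = np.asarray(posteriors, dtype=float)
    cutoffs = np.asarray(cutoffs, dtype=float)
    if posteriors.shape[1] != len(class_order) or len(cutoffs) != len(class_order):
        raise ValueError("posteriors/cutoffs width must match class_order")
    margin = posteriors - cutoffs[None, :]
    exceeds = margin >= 0.0
    picked = np.empty(len(posteriors), dtype=int)
    for i in range(len(posteriors)):
        pool = np.flatnonzero(exceeds[i])
        if len(pool) == 1:
            picked[i] = pool[0]
        else:
            # several or none: argmax margin, first index on exact ties
            picked[i] = int(np.argmax(margin[i]))
    return np.asarray(class_order, dtype=object)[picked]


def per_class_tpr(y_true: np.ndarray, y_pred: np.ndarray,
                  class_order: list[str]) -> dict[str, float]:
    """True-positive rate (recall, %) per class; NaN for absent classes."""
    out = {}
    for cls in class_order:
        mask = y_true == cls
        out[cls] = float(100.0 * np.mean(y_pred[mask] == cls)) if mask.any() else float("nan")
    return out


def overall_accuracy(per_class_tpr_pct, class_counts) -> float:
    """Prevalence-weighted overall accuracy (%) from per-class TPRs."""
    tpr = np.asarray(per_class_tpr_pct, dtype=float)
    n = np.asarray(class_counts, dtype=float)
    if len(tpr) != len(n):
        raise ValueError("tpr and class_counts lengths differ")
    return float(np.sum(n * tpr) / np.sum(n))


# ---------------------------------------------------------------------------
# model-series evaluation
# ---------------------------------------------------------------------------

@dataclass
class ModelEvaluation:
    """Cross-validated performance summary for one feature subset.

    ``auc_samples`` holds the macro AUC of each of the 50 test sets;
    accuracies (%) are per-fold values averaged across splits, at the
    default 0.5 cutoff and at the Youden-optimal cutoff.
    """

    n_features: int
    features: list[str]
    auc_samples: np.ndarray
    default_tpr: dict[str, float]
    default_overall: float
    optimal_tpr: dict[str, float]
    optimal_overall: float
    optimal_cutoffs: dict[str, float]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc_samples))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.auc_samples, ddof=1))


def _evaluate_split(train, test, features, hp, seed, class_order,
                    cutoff_mode: str):
    model = train_bagged_ensemble(train, features, hp, seed=seed)
    order = [str(c) for c in model.classes]
    post_test = model.predict_proba(test)
    y_test = test[OUTCOME_COLUMN].to_numpy()
    roc = roc_multiclass(post_test, y_test, order)

    # optimal cutoffs: from the training split (honest) or the test scores
    if cutoff_mode == "train":
        post_ref, y_ref = model.predict_proba(train), train[OUTCOME_COLUMN].to_numpy()
    elif cutoff_mode == "test":
        post_ref, y_ref = post_test, y_test
    else:
        raise ValueError(f"unknown cutoff_mode {cutoff_mode!r}")
    cutoffs = {}
    for j, cls in enumerate(order):
        try:
            cutoffs[cls] = optimal_cutoff(roc_one_vs_rest(post_ref[:, j], y_ref, cls))
        except ValueError:
            cutoffs[cls] = 0.5
    cut_arr = np.array([cutoffs[c] for c in order])

    pred_def = classify_at_cutoff(post_test, np.full(len(order), 0.5), order)
    pred_opt = classify_at_cutoff(post_test, cut_arr, order)
    tpr_def = per_class_tpr(y_test, pred_def, class_order)
    tpr_opt = per_class_tpr(y_test, pred_opt, class_order)
    acc_def = float(100.0 * np.mean(pred_def == y_test))
    acc_opt = float(100.0 * np.mean(pred_opt == y_test))
    return roc.macro_auc, tpr_def, acc_def, tpr_opt, acc_opt, cutoffs


def _nanmean_dicts(dicts, keys):
    return {k: float(np.nanmean([d[k] for d in dicts])) for k in keys}


def evaluate_subset(table: pd.DataFrame, features: list[str], scheme: CVScheme,
                    seed: int = 0, hp_budget: int = 30,
                    tune_mode: str = "per_subset",
                    cutoff_mode: str = "train",
                    hp: EnsembleHyperparams | None = None) -> ModelEvaluation:
    """Cross-validate one feature subset over the repeated stratified folds.

    ``tune_mode``: "per_subset" runs one hyperparameter search on the
    full table, "per_fold" re-tunes on every training split, "none"
    uses default hyperparameters.  A preset ``hp`` overrides the search
    entirely (unless tune_mode is "per_fold").  ``cutoff_mode``: where
    optimal cutoffs are estimated ("train" is the honest default,
    "test" pools the test scores).
    """
    folds = stratified_folds(table, scheme)
    class_order = sorted(table[OUTCOME_COLUMN].unique())
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(folds) + 1)
    sub_seed = int(children[-1].generate_state(1)[0] % (2**31))
    if hp is not None and tune_mode != "per_fold":
        pass
    elif tune_mode == "per_subset":
        hp = tune_hyperparams(table, features, budget=hp_budget, seed=sub_seed)
    elif tune_mode == "none":
        hp = EnsembleHyperparams()
    elif tune_mode != "per_fold":
        raise ValueError(f"unknown tune_mode {tune_mode!r}")
    aucs, tprs_d, accs_d, tprs_o, accs_o, cuts = [], [], [], [], [], []
    for (rep, fold, tr, te), child in zip(folds, children):
        split_seed = int(child.generate_state(1)[0] % (2**31))
        train, test = table.iloc[tr], table.iloc[te]
        if tune_mode == "per_fold":
            hp = tune_hyperparams(train, features, budget=hp_budget,
                                  seed=split_seed)
        auc, td, ad, to, ao, cut = _evaluate_split(
            train, test, features, hp, split_seed, class_order, cutoff_mode)
        aucs.append(auc)
        tprs_d.append(td)
        accs_d.append(ad)
        tprs_o.append(to)
        accs_o.append(ao)
        cuts.append(cut)
    return ModelEvaluation(
        n_features=len(features),
        features=list(features),
        auc_samples=np.asarray(aucs),
        default_tpr=_nanmean_dicts(tprs_d, class_order),
        default_overall=float(np.mean(accs_d)),
        optimal_tpr=_nanmean_dicts(tprs_o, class_order),
        optimal_overall=float(np.mean(accs_o)),
        optimal_cutoffs=_nanmean_dicts(cuts, class_order),
    )


def evaluate_model_series(series: NestedModelSeries, table: pd.DataFrame,
                          scheme: CVScheme, seed: int = 0,
                          hp_budget: int = 30,
                          tune_mode: str = "once",
                          cutoff_mode: str = "train") -> list[ModelEvaluation]:
    """Cross-validate every nested subset; one evaluation each, largest first.

    See :func:`evaluate_subset` for the "per_subset" / "per_fold" /
    "none" tuning modes; the default "once" runs a single hyperparameter
    search on the largest (full selected) subset and reuses it for the
    whole series — tree count and split cap transfer well across nested
    subsets of the same table.  Each subset gets its own deterministic
    sub-seed derived from ``seed``.
    """
    ss = np.random.SeedSequence((int(seed) + 1) * 7919)
    children = ss.spawn(len(series.sizes) + 1)
    sub_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    shared_hp = None
    mode = tune_mode
    if tune_mode == "once":
        shared_hp = tune_hyperparams(table, series.subsets[series.sizes[0]],
                                     budget=hp_budget, seed=sub_seeds[-1])
        mode = "none"
    return [
        evaluate_subset(table, series.subsets[size], scheme, seed=sub_seed,
                        hp_budget=hp_budget, tune_mode=mode,
                        cutoff_mode=cutoff_mode, hp=shared_hp)
        for size, sub_seed in zip(series.sizes, sub_seeds[:-1])
    ]


# ---------------------------------------------------------------------------
# statistics across models
# ---------------------------------------------------------------------------

def anova_one_way(groups) -> tuple[float, float]:
    """One-way ANOVA across groups of AUC samples: (F, p).

    Degenerate cases are defined explicitly: zero between-group variance
    gives F = 0, p = 1; zero within-group variance with distinct group
    means gives F = inf, p = 0.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    n = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n - k
    if ss_between <= 0:
        return 0.0, 1.0
    if ss_within <= 0:
        return float("inf"), 0.0
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(scipy.stats.f.sf(f, df_b, df_w))
    return float(f), p


def paired_ttest(a, b) -> tuple[float, float]:
    """Two-sided paired t-test on per-split differences: (t, p).

    A zero-variance difference is degenerate: t = 0, p = 1 when the
    constant difference is 0, otherwise t = +/-inf with p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.allclose(d, 0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    res = scipy.stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def select_best_and_optimal(evals: list[ModelEvaluation],
                            comparable_fraction: float = 0.95) -> tuple[int, int]:
    """(best, optimal) model sizes by mean AUC.

    Best: the subset size with the maximum mean AUC (ties -> fewer
    features).  Optimal: the smallest subset whose mean AUC exceeds
    ``comparable_fraction`` times the maximum.
    """
    if not evals:
        raise ValueError("no evaluations given")
    by_auc = sorted(evals, key=lambda e: (-e.mean_auc, e.n_features))
    best = by_auc[0]
    threshold = comparable_fraction * best.mean_auc
    eligible = [e for e in evals if e.mean_auc > threshold]
    optimal = min(eligible, key=lambda e: e.n_features)
    return best.n_features, optimal.n_features
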