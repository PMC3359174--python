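"""Nested cross-validation, adjusted accuracy, permutation control, chance bounds.

The evaluation protocol: stratified six-fold cross-validation, repeated
five times. Within each training fold, five independent GA runs select a
feature subset; the subset with the lowest training mean probability of
error trains the final LDA model, which is scored on the held-out fold.
The held-out fold never touches feature selection or model fitting. Scores
are adjusted accuracies — the unweighted mean of per-class percent-correct,
the k-class generalization of (sensitivity + specificity)/2 — which is
immune to the 2:1:1 class imbalance (144 NC vs 72 MA vs 72 MS). A
randomized-label control repeats the whole procedure and should land at
the ~33% three-class chance level; the chance-bound calculator gives the
accuracy threshold above which performance beats guessing at a given n and
alpha.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from . import ga as ga_mod
from . import lda as lda_mod
from .ga import Chromosome, GaConfig


def adjusted_accuracy(per_class_correct: Sequence[float]) -> float:
    """Unweighted mean of per-class percent-correct values (in %)."""
    vals = np.asarray(per_class_correct, dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one per-class value")
    if np.any((vals < 0) | (vals > 100)):
        raise ValueError("per-class percent-correct values must lie in [0, 100]")
    return float(vals.mean())


def make_folds(labels: Sequence, folds: int = 6, seed: int | None = 0) -> np.ndarray:
    """Stratified fold assignment: each fold holds 1/folds of each class (+-1)."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small!r} has {counts.min()} samples, fewer than {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment = np.empty(y.size, dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros((y.size, 1)), y)):
        assignment[test_idx] = f
    return assignment


def chance_upper_limit(
    k_classes: int, n_trials: int, alpha: float = 0.01, method: str = "adjusted-wald"
) -> float:
    """Upper confidence limit (in %) of chance-level accuracy.

    For n Bernoulli trials at chance proportion 1/k, returns the upper end
    of the two-sided (1 - alpha) interval. ``"adjusted-wald"`` uses the
    Agresti-Coull construction (z^2/2 successes and z^2 trials added before
    a Wald interval); ``"exact"`` uses the binomial quantile directly.
    Accuracies above this limit are significantly better than guessing.
    """
    if k_classes < 2:
        raise ValueError("need at least 2 classes")
    if n_trials < 1:
        raise ValueError("need at least 1 trial")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie strictly between 0 and 1")
    p0 = 1.0 / k_classes
    if method == "adjusted-wald":
        z = stats.norm.ppf(1 - alpha / 2)
        x = n_trials * p0
        n_adj = n_trials + z * z
        p_adj = (x + z * z / 2) / n_adj
        upper = p_adj + z * np.sqrt(p_adj * (1 - p_adj) / n_adj)
    elif method == "exact":
        upper = stats.binom.ppf(1 - alpha / 2, n_trials, p0) / n_trials
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(min(upper, 1.0) * 100.0)


@dataclass(eq=False)
class AccuracyReport:
    """Cross-validation outcome: per-fold, per-class and mean accuracies."""

    per_fold_adjusted: np.ndarray  # (runs * folds,) adjusted accuracies in %
    per_class_correct: dict[str, float]  # % correct pooled over all test folds
    mean_adjusted: float
    std_adjusted: float
    chosen_subsets: list[Chromosome] = field(default_factory=list)
    runs: int = 0
    folds: int = 0
    subset_dim: int = 0

    def to_dict(self) -> dict:
        return {
            "mean_adjusted": self.mean_adjusted,
            "std_adjusted": self.std_adjusted,
            "per_fold_adjusted": [float(v) for v in self.per_fold_adjusted],
            "per_class_correct": {k: float(v) for k, v in self.per_class_correct.items()},
            "chosen_subsets": [list(c.indices) for c in self.chosen_subsets],
            "runs": self.runs,
            "folds": self.folds,
            "subset_dim": self.subset_dim,
        }


def _fold_evaluation(X, y, train, test, ga_config, ga_runs, ga_seeds, ridge):
    """GA selection + LDA fit on the training rows; score on held-out rows."""
    X_tr, y_tr = X[train], y[train]
    fitness = lda_mod.resubstitution_error_fitness(X_tr, y_tr, ridge=ridge)
    results = [
        ga_mod.ga_run(None, None, ga_config, seed=int(s), fitness=fitness)
        for s in ga_seeds[:ga_runs]
    ]
    chosen = ga_mod.select_best_of_runs(results)
    cols = list(chosen.indices)
    model = lda_mod.lda_fit(X_tr[:, cols], y_tr, ridge=ridge)
    pred, _ = lda_mod.lda_predict(model, X[test][:, cols])
    return chosen, model.classes, pred


def nested_cv(
    X: np.ndarray,
    y: Sequence,
    ga_config: GaConfig | None = None,
    runs: int = 5,
    folds: int = 6,
    ga_runs_per_fold: int = 5,
    seed: int | None = 0,
    ridge: float | str = "auto",
) -> AccuracyReport:
    """The full classification procedure; returns runs x folds accuracies.

    At the defaults (5 repetitions of 6-fold CV) this yields the 30
    per-fold adjusted accuracies from which the mean is taken. Per-class
    percent-correct values are pooled over all test predictions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if ga_config is None:
        ga_config = GaConfig(search_space_dim=X.shape[1])
    ga_config.validate()
    rng = np.random.default_rng(seed)
    classes = np.unique(y)
    per_fold = []
    chosen_subsets: list[Chromosome] = []
    correct = {c: 0 for c in classes}
    totals = {c: 0 for c in classes}
    for _ in range(runs):
        fold_seed = int(rng.integers(2**31 - 1))
        assignment = make_folds(y, folds=folds, seed=fold_seed)
        for f in range(folds):
            ga_seeds = rng.integers(2**31 - 1, size=ga_runs_per_fold)
            test = np.flatnonzero(assignment == f)
            train = np.flatnonzero(assignment != f)
            chosen, model_classes, pred = _fold_evaluation(
                X, y, train, test, ga_config, ga_runs_per_fold, ga_seeds, ridge
            )
            chosen_subsets.append(chosen)
            rates = lda_mod.per_class_correct(y[test], pred, model_classes)
            per_fold.append(adjusted_accuracy(100.0 * rates))
            for c in classes:
                mask = y[test] == c
                correct[c] += int((pred[mask] == c).sum())
                totals[c] += int(mask.sum())
    per_fold = np.asarray(per_fold)
    pooled = {
        str(c): 100.0 * correct[c] / totals[c] if totals[c] else float("nan")
        for c in classes
    }
    return AccuracyReport(
        per_fold_adjusted=per_fold,
        per_class_correct=pooled,
        mean_adjusted=float(per_fold.mean()),
        std_adjusted=float(per_fold.std(ddof=1)) if per_fold.size > 1 else 0.0,
        chosen_subsets=chosen_subsets,
        runs=runs,
        folds=folds,
        subset_dim=ga_config.subset_dim,
    )


def permute_labels(y: Sequence, seed: int | None = 0) -> np.ndarray:
    """Uniform random permutation of the labels (class counts preserved)."""
    rng = np.random.default_rng(seed)
    return rng.permutation(np.asarray(y))


def randomized_label_control(
    X: np.ndarray,
    y: Sequence,
    ga_config: GaConfig | None = None,
    runs: int = 5,
    folds: int = 6,
    ga_runs_per_fold: int = 5,
    seed: int | None = 0,
) -> AccuracyReport:
    """The validity check: rerun the whole procedure on permuted labels.

    A properly leakage-free pipeline must score at chance (~33% for three
    classes) here, however well it does on the true labels.
    """
    rng = np.random.default_rng(seed)
    y_perm = permute_labels(y, seed=int(rng.integers(2**31 - 1)))
    return nested_cv(
        X, y_perm, ga_config=ga_config, runs=runs, folds=folds,
        ga_runs_per_fold=ga_runs_per_fold, seed=int(rng.integers(2**31 - 1)),
    )
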