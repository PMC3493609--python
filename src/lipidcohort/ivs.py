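"""Iterative variable selection (IVS) for PLS-DA classifiers.

IVS is a stochastic wrapper search that maximizes a cross-validated
objective (Q² by default).  One run: (1) randomly partition the candidate
features into subsets; (2) within each subset, greedily delete the
variable whose removal most improves the objective while any removal
improves it, then greedily re-add excluded variables the same way,
cycling until no single move improves the objective by more than the
convergence tolerance; (3) take the union of the subset-optimized sets
and repeat from (1) on the union until the outer objective stops
improving.  The objective is evaluated on a fold assignment fixed per run
so greedy move comparisons are noise-free, and the whole search is
deterministic given its seed.

An ensemble of independent runs (default 100) selects the run with
maximal Q²; a separate 7-repeat procedure with IVS embedded inside a
2/3-1/3 train/test split estimates how much the selection itself inflates
the reported performance (percent drop from training to held-out Q²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import ValidationError
from .multivariate import (
    DiscriminantModel,
    _cv_press,
    auroc,
    fit_opls_da,
    fit_preprocessor,
    partition_test_blocks,
    q_squared,
    stratified_folds,
)

__all__ = [
    "IVSConfig",
    "IVSResult",
    "ivs_run",
    "ivs_ensemble",
    "build_final_model",
    "overfitting_estimate",
]


@dataclass(frozen=True)
class IVSConfig:
    """Search configuration.

    ``n_subsets=None`` defaults to ``ceil(p / 20)`` so each random subset
    stays small enough for exhaustive single-move search.  The RNG is
    NumPy's PCG64 via ``default_rng``; run seeds are derived from ``seed``
    with ``SeedSequence.generate_state`` so the first k runs of an
    ensemble are identical for any ``n_runs >= k``.
    """

    n_subsets: int | None = None
    objective: str = "q2"
    max_outer_iterations: int = 10
    convergence_tolerance: float = 1e-4
    n_runs: int = 100
    seed: int = 0
    n_components: int = 2
    n_folds: int = 7

    def __post_init__(self) -> None:
        if self.n_subsets is not None and self.n_subsets < 1:
            raise ValidationError("n_subsets must be >= 1")
        if self.objective not in ("q2", "r2"):
            raise ValidationError("objective must be 'q2' or 'r2'")
        if self.convergence_tolerance <= 0:
            raise ValidationError("convergence tolerance must be positive")
        if self.n_runs < 1 or self.max_outer_iterations < 1:
            raise ValidationError("n_runs and max_outer_iterations must be >= 1")


@dataclass
class IVSResult:
    """Outcome of a single IVS run."""

    selected_variables: list[str]
    objective_trajectory: list[float]
    run_seed: int
    final_q2: float
    n_evaluations: int = 0


class _Objective:
    """Cached CV objective over feature subsets, fixed folds per run."""

    def __init__(self, Xlog, y, folds, n_components, kind):
        self.Xlog = Xlog
        self.y = y
        self.folds = folds
        self.n_components = n_components
        self.kind = kind
        self.cache: dict[frozenset, float] = {}
        self.n_evaluations = 0

    def __call__(self, subset: tuple[int, ...]) -> float:
        key = frozenset(subset)
        if key in self.cache:
            return self.cache[key]
        cols = np.fromiter(sorted(subset), dtype=int)
        a = min(self.n_components, len(cols))
        if self.kind == "q2":
            press, tss = _cv_press(self.Xlog[:, cols], self.y, self.folds, a)
            val = 1.0 - press / tss
        else:
            # in-sample R² on the full data (no held-out folds)
            from .multivariate import fit_pls_da, fit_preprocessor

            pre = fit_preprocessor(self.Xlog[:, cols], log=False)
            val = fit_pls_da(pre.transform(self.Xlog[:, cols]), self.y, a).r2y
        self.cache[key] = val
        self.n_evaluations += 1
        return val


def _optimize_subset(
    subset: list[int],
    objective: _Objective,
    tol: float,
    names: list[str],
) -> tuple[list[int], float]:
    """Backward deletion then forward addition, cycled to 1-move optimality.

    Ties on equal objective gain are broken by the lexicographically first
    variable name, independent of seed.
    """
    current = sorted(subset)
    excluded: list[int] = []
    best = objective(tuple(current))
    while True:
        changed = False
        # backward pass: fully converge deletions first
        while len(current) > 1:
            candidates = []
            for f in current:
                trial = [g for g in current if g != f]
                candidates.append((objective(tuple(trial)) - best, names[f], f))
            gain, _, f = max(candidates, key=lambda c: (c[0], _neg_name(c[1])))
            if gain > tol:
                current.remove(f)
                excluded.append(f)
                best += gain
                changed = True
            else:
                break
        # forward pass: re-add excluded variables while it helps
        while excluded:
            candidates = []
            for f in excluded:
                trial = sorted(current + [f])
                candidates.append((objective(tuple(trial)) - best, names[f], f))
            gain, _, f = max(candidates, key=lambda c: (c[0], _neg_name(c[1])))
            if gain > tol:
                excluded.remove(f)
                current = sorted(current + [f])
                best += gain
                changed = True
            else:
                break
        if not changed:
            return current, best


class _neg_name(str):
    """Reverses string comparison so max() prefers the lexicographically
    first name on exact objective ties."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)


def ivs_run(X, y, feature_names, config: IVSConfig, run_seed: int) -> IVSResult:
    """One deterministic IVS optimization (see module docstring).

    ``X`` is the raw positive concentration matrix; log transform is
    applied here and centering/scaling are refitted inside every CV fold.
    """
    X = np.asarray(X, dtype=float)
    names = list(feature_names)
    n, p = X.shape
    if p < 2:
        raise ValidationError("IVS needs at least two candidate features")
    if len(names) != p:
        raise ValidationError("feature_names length must match X columns")
    rng = np.random.default_rng(run_seed)
    y = np.asarray(y, dtype=float).ravel()
    folds = stratified_folds(y, min(config.n_folds, n), rng)
    objective = _Objective(np.log(X), y, folds, config.n_components, config.objective)

    n_subsets = config.n_subsets or math.ceil(p / 20)
    tol = config.convergence_tolerance
    current = list(range(p))
    best = objective(tuple(current))
    trajectory = [best]
    for _ in range(config.max_outer_iterations):
        perm = rng.permutation(len(current))
        k = min(n_subsets, len(current))
        parts = [sorted(current[i] for i in perm[j::k]) for j in range(k)]
        union: set[int] = set()
        for part in parts:
            opt, _ = _optimize_subset(part, objective, tol, names)
            union.update(opt)
        candidate = sorted(union)
        if not candidate:
            break
        cand_obj = objective(tuple(candidate))
        if cand_obj > best + tol:
            current, best = candidate, cand_obj
            trajectory.append(best)
        else:
            break
    if config.objective == "q2":
        final_q2 = best
    else:
        cols = np.array(current, dtype=int)
        press, tss = _cv_press(
            np.log(X[:, cols]), y, folds, min(config.n_components, len(cols))
        )
        final_q2 = 1.0 - press / tss
    return IVSResult(
        selected_variables=[names[i] for i in current],
        objective_trajectory=trajectory,
        run_seed=int(run_seed),
        final_q2=final_q2,
        n_evaluations=objective.n_evaluations,
    )


def ivs_ensemble(
    X, y, feature_names, config: IVSConfig
) -> tuple[IVSResult, list[IVSResult]]:
    """Run ``config.n_runs`` independent IVS searches; return the best.

    The best run maximizes Q²; exact ties prefer the smaller selected set,
    then the lower run index.
    """
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_runs)
    runs = [
        ivs_run(X, y, feature_names, config, int(s)) for s in seeds
    ]
    best_i = max(
        range(len(runs)),
        key=lambda i: (runs[i].final_q2, -len(runs[i].selected_variables), -i),
    )
    return runs[best_i], runs


def build_final_model(
    X,
    y,
    feature_names,
    selected: list[str],
    n_orthogonal: int = 1,
) -> tuple[DiscriminantModel, "object"]:
    """Fit the reporting OPLS-DA model on the selected variables.

    Returns ``(model, preprocessor)``; the predictive component is
    oriented so that class-1-elevated features load positive, and loading
    order follows the selected-variable order for loading-plot export.
    """
    if not selected:
        raise ValidationError("selection must be nonempty")
    names = list(feature_names)
    cols = [names.index(s) for s in selected]
    X = np.asarray(X, dtype=float)[:, cols]
    y = np.asarray(y, dtype=float).ravel()
    pre = fit_preprocessor(X, log=True, feature_names=selected)
    Z = pre.transform(X)
    n_orth = min(n_orthogonal, min(Z.shape) - 1)
    model = fit_opls_da(Z, y, n_orthogonal=n_orth, feature_names=selected)
    # orient: mean predictive score of class 1 positive
    t = model.scores[:, 0]
    if t[y == 1].mean() < t[y == 0].mean():
        model.weights = -model.weights
        model.scores = -model.scores
        model.loadings = -model.loadings
        model.y_loadings = -model.y_loadings
    return model, pre


def overfitting_estimate(
    X,
    y,
    feature_names,
    config: IVSConfig,
    n_validations: int = 7,
    sub_runs: int = 100,
    train_fraction: float = 2.0 / 3.0,
    seed: int | None = None,
) -> tuple[float, float, list[dict]]:
    """Estimate selection-induced optimism by IVS-embedded validation.

    For each of ``n_validations`` stratified 2/3-1/3 splits, ``sub_runs``
    IVS optimizations run on the training portion alone; the winning
    selection's training Q² is compared with its held-out test-set Q².
    Returns ``(mean_pct_drop, sd_pct_drop, details)`` where the percent
    drop is 100·(train − test)/train for positive training Q² and
    100·(train − test) in absolute Q² points otherwise (a signal-free
    model has no meaningful relative scale).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = len(y)
    drops: list[float] = []
    details: list[dict] = []
    for v in range(n_validations):
        test = _stratified_test_split(y, 1.0 - train_fraction, rng)
        train = np.setdiff1d(np.arange(n), test)
        sub_cfg = replace(config, n_runs=sub_runs, seed=int(rng.integers(2**31)))
        best, _ = ivs_ensemble(X[train], y[train], feature_names, sub_cfg)
        names = list(feature_names)
        cols = [names.index(s) for s in best.selected_variables]
        train_q2 = best.final_q2
        pre = fit_preprocessor(X[np.ix_(train, cols)], log=True)
        model = fit_opls_da(
            pre.transform(X[np.ix_(train, cols)]),
            y[train],
            n_orthogonal=min(1, len(cols) - 1) if len(cols) > 1 else 0,
        )
        pred = model.predict(pre.transform(X[np.ix_(test, cols)]))
        ym = y[train].mean()
        test_q2 = 1.0 - float(
            ((y[test] - pred) ** 2).sum() / ((y[test] - ym) ** 2).sum()
        )
        if train_q2 > 1e-6:
            drop = 100.0 * (train_q2 - test_q2) / train_q2
        else:
            drop = 100.0 * (train_q2 - test_q2)
        drops.append(drop)
        details.append(
            {
                "validation": v,
                "selected": best.selected_variables,
                "train_q2": train_q2,
                "test_q2": test_q2,
                "pct_drop": drop,
            }
        )
    return (
        float(np.mean(drops)),
        float(np.std(drops, ddof=1)) if len(drops) > 1 else 0.0,
        details,
    )


def _stratified_test_split(y, test_fraction: float, rng) -> np.ndarray:
    """One stratified test set of about ``test_fraction`` of each class."""
    test: list[int] = []
    for label in np.unique(y):
        idx = np.flatnonzero(y == label)
        idx = idx[rng.permutation(len(idx))]
        k = max(1, int(round(test_fraction * len(idx))))
        k = min(k, len(idx) - 2)  # keep >= 2 per class in training
        test.extend(int(i) for i in idx[:k])
    return np.sort(np.array(test, dtype=int))
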