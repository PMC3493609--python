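"""NIPALS PLS-DA and OPLS-DA with cross-validated Q², AUROC and
repeated 2/3-1/3 external validation.

Discriminant models are fitted on log-transformed, mean-centered,
unit-variance-scaled concentrations against a binary class vector coded
{0,1} and centered.  PLS components are extracted by NIPALS with
deterministic deflation (no randomized initialization; for a single
response the first weight vector is proportional to X'y).  OPLS-DA
iteratively removes orthogonal-signal components — variation in X with
exactly zero sample correlation to y — and fits one predictive latent
variable on the filtered matrix; its fitted values coincide with those of
a PLS model carrying one extra component.

Q² = 1 - PRESS/TSS is estimated by stratified k-fold cross-validation
(default 7 folds) with the preprocessing refitted inside each training
fold; AUROC is the Mann-Whitney concordance probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import ValidationError

__all__ = [
    "Preprocessor",
    "DiscriminantModel",
    "ValidationReport",
    "fit_preprocessor",
    "fit_pls_da",
    "fit_opls_da",
    "q_squared",
    "auroc",
    "external_validation",
    "stratified_folds",
]


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


@dataclass
class Preprocessor:
    """Log / center / unit-variance scaling fitted on training rows only."""

    center: np.ndarray
    scale: np.ndarray
    log: bool = True
    feature_names: list[str] | None = None

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.log:
            if np.any(X <= 0):
                raise ValidationError("log preprocessing requires positive data")
            X = np.log(X)
        return (X - self.center) / self.scale

    def inverse_transform(self, Z) -> np.ndarray:
        X = np.asarray(Z, dtype=float) * self.scale + self.center
        return np.exp(X) if self.log else X


def fit_preprocessor(X, log: bool = True, feature_names=None) -> Preprocessor:
    """Fit log-center-scale parameters; errors on zero-variance features."""
    X = np.asarray(X, dtype=float)
    if log:
        if np.any(X <= 0):
            raise ValidationError("log preprocessing requires strictly positive data")
        X = np.log(X)
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    tiny = scale <= 1e-10 * np.maximum(1.0, np.abs(center))
    if np.any(tiny):
        j = int(np.argmax(tiny))
        name = feature_names[j] if feature_names is not None else f"column {j}"
        raise ValidationError(f"feature {name!r} has zero variance; cannot scale")
    return Preprocessor(center=center, scale=scale, log=log,
                        feature_names=list(feature_names) if feature_names else None)


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


@dataclass
class DiscriminantModel:
    """A fitted (O)PLS-DA model on preprocessed data.

    For PLS-DA the arrays hold all extracted components; for OPLS-DA the
    predictive part is a single component and the orthogonal part holds
    ``n_orthogonal`` components.
    """

    kind: str
    weights: np.ndarray           # p x A predictive weights
    loadings: np.ndarray          # p x A predictive loadings
    scores: np.ndarray            # n x A predictive scores (training)
    y_loadings: np.ndarray        # A
    coef: np.ndarray              # p regression vector (centered-y scale)
    y_mean: float
    r2y: float
    n_predictive: int
    n_orthogonal: int = 0
    ortho_weights: np.ndarray | None = None
    ortho_loadings: np.ndarray | None = None
    ortho_scores: np.ndarray | None = None
    feature_names: list[str] | None = None
    auroc_train: float | None = None
    threshold: float = 0.0

    def _filter(self, X: np.ndarray) -> np.ndarray:
        if self.n_orthogonal:
            X = X.copy()
            for k in range(self.n_orthogonal):
                t_o = X @ self.ortho_weights[:, k]
                X -= np.outer(t_o, self.ortho_loadings[:, k])
        return X

    def predict(self, X) -> np.ndarray:
        """Predicted class value on the original {0,1} coding."""
        X = np.asarray(X, dtype=float)
        return self._filter(X) @ self.coef + self.y_mean

    def predictive_scores(self, X) -> np.ndarray:
        X = self._filter(np.asarray(X, dtype=float))
        return X @ self.weights[:, : self.n_predictive]

    def classify(self, X) -> np.ndarray:
        return (self.predict(X) >= self.threshold).astype(int)

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "n_predictive": self.n_predictive,
            "n_orthogonal": self.n_orthogonal,
            "r2y": self.r2y,
            "auroc_train": self.auroc_train,
            "y_mean": self.y_mean,
            "threshold": self.threshold,
            "feature_names": self.feature_names,
            "weights": self.weights.tolist(),
            "loadings": self.loadings.tolist(),
            "scores": self.scores.tolist(),
            "y_loadings": np.asarray(self.y_loadings).tolist(),
            "coef": self.coef.tolist(),
        }
        if self.n_orthogonal:
            d["ortho_weights"] = self.ortho_weights.tolist()
            d["ortho_loadings"] = self.ortho_loadings.tolist()
            d["ortho_scores"] = self.ortho_scores.tolist()
        return d


def _check_Xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValidationError("X must be 2-D with one row per label")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("labels must be coded {0, 1}")
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present")
    return X, y


def _nipals_pls1(X: np.ndarray, yc: np.ndarray, n_components: int):
    """NIPALS PLS with a single centered response.

    Returns (W, P, q, T) with normalized weights, X-loadings, y-loadings
    and training scores.  Deterministic: the a-th weight vector is the
    normalized X_a'y of the a-times-deflated matrix.
    """
    n, p = X.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    Xa = X.copy()
    for a in range(n_components):
        w = Xa.T @ yc
        norm = np.linalg.norm(w)
        if norm < 1e-12 * max(1.0, np.linalg.norm(Xa)):
            raise ValidationError(
                f"component {a + 1} exceeds the predictive rank of X"
            )
        w /= norm
        t = Xa @ w
        tt = t @ t
        if tt < 1e-24:
            raise ValidationError(f"degenerate score vector at component {a + 1}")
        pvec = Xa.T @ t / tt
        q[a] = yc @ t / tt
        Xa -= np.outer(t, pvec)
        W[:, a], P[:, a], T[:, a] = w, pvec, t
    return W, P, q, T


def _pls1_coef(W, P, q) -> np.ndarray:
    return W @ np.linalg.solve(P.T @ W, q)


def fit_pls_da(X, y, n_components: int = 2, feature_names=None) -> DiscriminantModel:
    """PLS-DA by NIPALS on preprocessed X and {0,1} labels."""
    X, y = _check_Xy(X, y)
    if n_components < 1 or n_components > min(X.shape):
        raise ValidationError(
            f"n_components must be in [1, {min(X.shape)}], got {n_components}"
        )
    y_mean = float(y.mean())
    yc = y - y_mean
    W, P, q, T = _nipals_pls1(X, yc, n_components)
    coef = _pls1_coef(W, P, q)
    yhat = X @ coef
    r2y = 1.0 - float(((yc - yhat) ** 2).sum() / (yc**2).sum())
    pred = yhat + y_mean
    model = DiscriminantModel(
        kind="PLS-DA",
        weights=W,
        loadings=P,
        scores=T,
        y_loadings=q,
        coef=coef,
        y_mean=y_mean,
        r2y=r2y,
        n_predictive=n_components,
        feature_names=list(feature_names) if feature_names is not None else None,
    )
    model.auroc_train = auroc(pred, y)
    model.threshold = float(
        (pred[y == 1].mean() + pred[y == 0].mean()) / 2.0
    )
    return model


def fit_opls_da(X, y, n_orthogonal: int = 1, feature_names=None) -> DiscriminantModel:
    """OPLS-DA: remove y-orthogonal components, fit one predictive LV.

    With ``n_orthogonal = 0`` this reduces exactly to 1-component PLS-DA.
    Orthogonal score vectors have zero sample correlation with y by
    construction (their weights are orthogonal to X'y).
    """
    X, y = _check_Xy(X, y)
    if n_orthogonal < 0 or n_orthogonal > min(X.shape) - 1:
        raise ValidationError(
            f"n_orthogonal must be in [0, {min(X.shape) - 1}], got {n_orthogonal}"
        )
    y_mean = float(y.mean())
    yc = y - y_mean
    w = X.T @ yc
    norm = np.linalg.norm(w)
    if norm < 1e-12:
        raise ValidationError("X carries no predictive signal (X'y = 0)")
    w /= norm

    p_feat = X.shape[1]
    Wo = np.zeros((p_feat, n_orthogonal))
    Po = np.zeros((p_feat, n_orthogonal))
    To = np.zeros((X.shape[0], n_orthogonal))
    Xf = X.copy()
    for k in range(n_orthogonal):
        t = Xf @ w
        pvec = Xf.T @ t / (t @ t)
        w_o = pvec - (w @ pvec) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:
            raise ValidationError(
                f"no orthogonal variation left at component {k + 1}"
            )
        w_o /= n_o
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf -= np.outer(t_o, p_o)
        Wo[:, k], Po[:, k], To[:, k] = w_o, p_o, t_o

    t = Xf @ w
    tt = t @ t
    pvec = Xf.T @ t / tt
    q = float(yc @ t / tt)
    coef = w * q
    yhat = Xf @ coef
    r2y = 1.0 - float(((yc - yhat) ** 2).sum() / (yc**2).sum())
    pred = yhat + y_mean
    model = DiscriminantModel(
        kind="OPLS-DA",
        weights=w[:, None],
        loadings=pvec[:, None],
        scores=t[:, None],
        y_loadings=np.array([q]),
        coef=coef,
        y_mean=y_mean,
        r2y=r2y,
        n_predictive=1,
        n_orthogonal=n_orthogonal,
        ortho_weights=Wo,
        ortho_loadings=Po,
        ortho_scores=To,
        feature_names=list(feature_names) if feature_names is not None else None,
    )
    model.auroc_train = auroc(pred, y)
    model.threshold = float((pred[y == 1].mean() + pred[y == 0].mean()) / 2.0)
    return model


# ---------------------------------------------------------------------------
# Performance statistics
# ---------------------------------------------------------------------------


def auroc(scores, labels) -> float:
    """AUROC as the concordance probability P(s+ > s-) + P(tie)/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUROC requires both classes present")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def stratified_folds(y, n_folds: int, rng) -> list[np.ndarray]:
    """Class-stratified fold assignment; every fold keeps both classes."""
    y = np.asarray(y)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    offset = 0  # running counter so folds fill evenly across classes
    for label in np.unique(y):
        idx = np.flatnonzero(y == label)
        idx = idx[rng.permutation(len(idx))]
        for i, j in enumerate(idx):
            folds[(offset + i) % n_folds].append(int(j))
        offset += len(idx)
    out = [np.sort(np.array(f, dtype=int)) for f in folds]
    if any(len(f) == 0 for f in out):
        raise ValidationError("more folds than subjects; some folds are empty")
    for f in out:
        if len(np.unique(y[f])) < 2 and len(y) - len(f) > 0:
            held_in = np.unique(y[np.setdiff1d(np.arange(len(y)), f)])
            if len(held_in) < 2:
                raise ValidationError("a training fold lost one class entirely")
    return out


def _venetian_folds(y, n_folds: int) -> list[np.ndarray]:
    """SIMCA-style venetian-blind assignment: every n_folds-th sample."""
    n = len(np.asarray(y))
    return [np.arange(k, n, n_folds) for k in range(n_folds)]


def _cv_press(
    Xlog: np.ndarray,
    y: np.ndarray,
    folds: list[np.ndarray],
    n_components: int,
    n_orthogonal: int | None = None,
) -> tuple[float, float]:
    """PRESS/TSS over held-out folds; preprocessing refit per training fold.

    ``Xlog`` is log-transformed but not centered/scaled.  Internal fast
    path shared with the variable-selection wrapper.
    """
    press = tss = 0.0
    n = len(y)
    for test in folds:
        train = np.setdiff1d(np.arange(n), test)
        if len(np.unique(y[train])) < 2:
            raise ValidationError(f"training fold for test block {test} lost a class")
        mu = Xlog[train].mean(axis=0)
        sd = Xlog[train].std(axis=0, ddof=1)
        if np.any(sd <= 1e-12 * np.maximum(1.0, np.abs(mu))):
            raise ValidationError(
                f"zero-variance feature inside fold with test block {test}"
            )
        Xt = (Xlog[train] - mu) / sd
        Xe = (Xlog[test] - mu) / sd
        ym = y[train].mean()
        yc = y[train] - ym
        a = min(n_components, min(Xt.shape))
        if n_orthogonal is None:
            W, P, q, _ = _nipals_pls1(Xt, yc, a)
            pred = Xe @ _pls1_coef(W, P, q)
        else:
            m = fit_opls_da(Xt, y[train], n_orthogonal=n_orthogonal)
            pred = m.predict(Xe) - ym
        press += float(((y[test] - ym - pred) ** 2).sum())
        tss += float(((y[test] - ym) ** 2).sum())
    return press, tss


def q_squared(
    X,
    y,
    n_components: int = 2,
    n_orthogonal: int | None = None,
    n_folds: int = 7,
    fold_scheme: str = "stratified",
    seed: int = 0,
    log: bool = True,
) -> float:
    """Cross-validated Q² = 1 - PRESS/TSS for a PLS-DA or OPLS-DA spec.

    ``X`` is raw (positive) data when ``log=True``.  Folds are stratified
    by class (seeded) or venetian-blind; preprocessing is refitted within
    each training fold and TSS is taken about the training-fold mean of
    the centered class vector.
    """
    X, y = _check_Xy(X, y)
    if n_folds < 2 or n_folds > len(y):
        raise ValidationError("n_folds must be in [2, n subjects]")
    Xlog = np.log(X) if log else X.astype(float)
    if fold_scheme == "stratified":
        folds = stratified_folds(y, n_folds, np.random.default_rng(seed))
    elif fold_scheme == "venetian":
        folds = _venetian_folds(y, n_folds)
    else:
        raise ValidationError(f"unknown fold scheme {fold_scheme!r}")
    for f in folds:
        if len(np.unique(y[np.setdiff1d(np.arange(len(y)), f)])) < 2:
            raise ValidationError("a fold leaves a single-class training set")
    press, tss = _cv_press(Xlog, y, folds, n_components, n_orthogonal)
    return 1.0 - press / tss


# ---------------------------------------------------------------------------
# External validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Repeated stratified 2/3-1/3 external validation."""

    test_sets: list[np.ndarray]
    train_q2: list[float]
    test_q2: list[float]
    test_auroc: list[float]
    extras: dict = field(default_factory=dict)

    @property
    def mean_test_q2(self) -> float:
        return float(np.mean(self.test_q2))

    @property
    def sd_test_q2(self) -> float:
        return float(np.std(self.test_q2, ddof=1))

    @property
    def mean_test_auroc(self) -> float:
        return float(np.mean(self.test_auroc))

    @property
    def sd_test_auroc(self) -> float:
        return float(np.std(self.test_auroc, ddof=1))


def partition_test_blocks(y, repeats: int, rng) -> list[np.ndarray]:
    """Stratified near-equal test blocks that exactly partition the cohort."""
    y = np.asarray(y)
    blocks: list[list[int]] = [[] for _ in range(repeats)]
    for label in np.unique(y):
        idx = np.flatnonzero(y == label)
        idx = idx[rng.permutation(len(idx))]
        base, rem = divmod(len(idx), repeats)
        sizes = [base] * (repeats - rem) + [base + 1] * rem
        start = 0
        for b, size in enumerate(sizes):
            blocks[b].extend(int(i) for i in idx[start : start + size])
            start += size
    return [np.sort(np.array(b, dtype=int)) for b in blocks]


def external_validation(
    X,
    y,
    repeats: int = 3,
    n_orthogonal: int = 1,
    n_folds: int = 7,
    seed: int = 0,
    log: bool = True,
) -> ValidationReport:
    """Repeat OPLS-DA training/testing so each subject is tested once.

    The cohort is split, stratified by class, into ``repeats`` near-equal
    test blocks; for each block the remaining ~2/3 of subjects train an
    OPLS-DA model (preprocessing fitted on the training rows only) whose
    internal Q², held-out Q² and held-out AUROC are reported per repeat
    and as mean ± sd.
    """
    X, y = _check_Xy(X, y)
    rng = np.random.default_rng(seed)
    test_sets = partition_test_blocks(y, repeats, rng)
    Xlog = np.log(X) if log else X.astype(float)
    train_q2, test_q2, test_auroc = [], [], []
    for test in test_sets:
        train = np.setdiff1d(np.arange(len(y)), test)
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            raise ValidationError("split left a single-class train or test set")
        pre = fit_preprocessor(np.exp(Xlog[train]) if log else Xlog[train], log=log)
        Zt = pre.transform(np.exp(Xlog[train]) if log else Xlog[train])
        Ze = pre.transform(np.exp(Xlog[test]) if log else Xlog[test])
        model = fit_opls_da(Zt, y[train], n_orthogonal=n_orthogonal)
        train_q2.append(
            q_squared(
                np.exp(Xlog[train]) if log else Xlog[train],
                y[train],
                n_orthogonal=n_orthogonal,
                n_folds=min(n_folds, len(train)),
                seed=seed,
                log=log,
            )
        )
        ym = y[train].mean()
        pred = model.predict(Ze)
        test_q2.append(
            1.0
            - float(((y[test] - pred) ** 2).sum() / ((y[test] - ym) ** 2).sum())
        )
        test_auroc.append(auroc(pred, y[test]))
    return ValidationReport(
        test_sets=test_sets,
        train_q2=train_q2,
        test_q2=test_q2,
        test_auroc=test_auroc,
    )
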