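"""Multivariate engine: PCA, OPLS-DA with VIP, cross-validated R2Y/Q2.

Both models operate on log-transformed, imputed intensities, autoscaled
(mean-centered, unit variance) by default — standard practice for
untargeted metabolomics where fold changes matter more than absolute
abundance.

The discriminant model is an orthogonal projection to latent structures
(O-PLS) for a single binary response: y-orthogonal variation is stripped
component by component, then a single predictive PLS component is fit on
the filtered matrix. With ``n_ortho=0`` the model reduces exactly to
one-component PLS1, which is the cross-check used in the test suite.

Variable importance in projection (VIP) is computed over predictive
components and normalized so that the mean of VIP^2 across features is 1;
the conventional VIP > 1 cut therefore flags features carrying more than
an average share of the class-predictive variance.

Sign convention: for every score/loading (and the predictive weight) the
element of largest magnitude is made positive, so fits are byte-reproducible
across BLAS builds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .tables_io import FeatureTable


def log_intensities(table: FeatureTable, base: float = 2.0) -> pd.DataFrame:
    """Log-transform an imputed table (no missing, strictly positive)."""
    v = table.values
    if v.isna().any().any():
        raise ValueError("log transform requires an imputed table (no missing cells)")
    if (v.to_numpy() <= 0).any():
        raise ValueError("log transform requires strictly positive intensities")
    return np.log(v) / np.log(base)


def _autoscale(
    X: np.ndarray, scale: bool, feature_names: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    Xc = X - center
    if scale:
        sd = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            names = [feature_names[i] for i in zero[:5]]
            raise ValueError(
                f"constant feature(s) under unit-variance scaling: {names}"
            )
        Xc = Xc / sd
    else:
        sd = np.ones_like(center)
    return Xc, center, sd


def _fix_sign(vector: np.ndarray) -> float:
    """Return -1/+1 so that the largest-magnitude element becomes positive."""
    i = int(np.argmax(np.abs(vector)))
    return -1.0 if vector[i] < 0 else 1.0


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaModel:
    """PCA fit: scores (samples x k), orthonormal loadings (features x k),
    explained-variance fractions, and the centering/scaling vectors."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_fraction: np.ndarray
    center: np.ndarray
    scale: np.ndarray


def fit_pca(
    X: pd.DataFrame, k: int = 2, scale: bool = True
) -> PcaModel:
    """Principal component analysis via singular value decomposition."""
    if X.isna().any().any():
        raise ValueError("PCA requires a complete matrix (impute first)")
    n, p = X.shape
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k must be in [1, {min(n - 1, p)}], got {k}")
    Xs, center, sd = _autoscale(X.to_numpy(dtype=float), scale, list(X.columns))
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    explained = (s**2 / np.sum(s**2))[:k]
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    for a in range(k):
        flip = _fix_sign(loadings[:, a])
        loadings[:, a] *= flip
        scores[:, a] *= flip
    comp = [f"PC{a + 1}" for a in range(k)]
    return PcaModel(
        scores=pd.DataFrame(scores, index=X.index, columns=comp),
        loadings=pd.DataFrame(loadings, index=X.columns, columns=comp),
        explained_variance_fraction=explained,
        center=center,
        scale=sd,
    )


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------


@dataclass
class OplsModel:
    """Fitted OPLS-DA model for one binary comparison.

    Predictive part: weights ``w``, scores ``t``, loadings ``p`` and the
    inner regression coefficient ``q`` (prediction is ``t*q + y_mean``).
    Orthogonal part: ``n_ortho`` (weights, scores, loadings) triples.
    ``r2y`` is the fitted class-variance fraction, ``q2`` the
    cross-validated one (``None`` until cross-validation runs), ``vip`` the
    per-feature importance.
    """

    classes: tuple[str, str]
    feature_names: list[str]
    w: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q: float
    w_ortho: np.ndarray  # features x n_ortho
    t_ortho: np.ndarray  # samples x n_ortho
    p_ortho: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    y_mean: float
    r2y: float
    vip: pd.Series
    q2: float | None = None

    @property
    def n_ortho(self) -> int:
        return self.w_ortho.shape[1]

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Numeric class prediction for new samples (same feature order)."""
        Xn = np.asarray(X, dtype=float)
        E = (Xn - self.center) / self.scale
        for a in range(self.n_ortho):
            t_o = E @ self.w_ortho[:, a]
            E = E - np.outer(t_o, self.p_ortho[:, a])
        return E @ self.w * self.q + self.y_mean


def encode_response(labels: Sequence[str]) -> tuple[np.ndarray, tuple[str, str]]:
    """Encode a two-class label vector as 1 (first class) / 0 (second).

    Classes are ordered by first appearance so ``("GL", "XZ")`` keeps the
    comparison orientation of the input.
    """
    classes = list(dict.fromkeys(labels))
    if len(classes) != 2:
        raise ValueError(f"expected exactly two classes, got {classes}")
    y = np.array([1.0 if g == classes[0] else 0.0 for g in labels])
    counts = [int(y.sum()), int(len(y) - y.sum())]
    if min(counts) < 2:
        raise ValueError(f"each class needs >= 2 samples, got {dict(zip(classes, counts))}")
    return y, (classes[0], classes[1])


def _opls_core(
    Xc: np.ndarray, yc: np.ndarray, n_ortho: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, np.ndarray, np.ndarray, np.ndarray]:
    """Trygg-Wold orthogonal filtering + one predictive PLS component.

    Operates on a centered/scaled X and centered y; returns
    (w, t, p, q, W_o, T_o, P_o).
    """
    p_feat = Xc.shape[1]
    W_o = np.zeros((p_feat, n_ortho))
    T_o = np.zeros((Xc.shape[0], n_ortho))
    P_o = np.zeros((p_feat, n_ortho))
    E = Xc.copy()
    for a in range(n_ortho):
        w = E.T @ yc
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError("response uncorrelated with every feature; cannot fit")
        w /= norm
        t = E @ w
        p_load = E.T @ t / (t @ t)
        w_o = p_load - (w @ p_load) * w
        norm_o = np.linalg.norm(w_o)
        if norm_o < 1e-12:
            raise ValueError(
                f"no y-orthogonal variation left for component {a + 1}; "
                "reduce n_ortho"
            )
        w_o /= norm_o
        t_o = E @ w_o
        p_o = E.T @ t_o / (t_o @ t_o)
        E = E - np.outer(t_o, p_o)
        W_o[:, a], T_o[:, a], P_o[:, a] = w_o, t_o, p_o
    w = E.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("response uncorrelated with every feature; cannot fit")
    w /= norm
    t = E @ w
    p_load = E.T @ t / (t @ t)
    q = float(yc @ t / (t @ t))
    return w, t, p_load, q, W_o, T_o, P_o


def _vip_from_components(
    w_cols: np.ndarray, t_cols: np.ndarray, yc: np.ndarray
) -> np.ndarray:
    """VIP over given components: vip_j^2 = p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a."""
    p_feat = w_cols.shape[0]
    ssy = np.array(
        [
            (yc @ t_cols[:, a]) ** 2 / (t_cols[:, a] @ t_cols[:, a])
            for a in range(w_cols.shape[1])
        ]
    )
    if ssy.sum() == 0:
        raise ValueError("zero explained response variance; VIP undefined")
    wnorm2 = (w_cols / np.linalg.norm(w_cols, axis=0)) ** 2
    return np.sqrt(p_feat * (wnorm2 @ ssy) / ssy.sum())


def fit_oplsda(
    X: pd.DataFrame,
    labels: Sequence[str],
    n_ortho: int = 1,
    scale: bool = True,
    cv: str | int | None = None,
    cv_seed: int = 0,
) -> OplsModel:
    """Fit OPLS-DA for a two-class comparison.

    Parameters
    ----------
    X
        samples x features matrix (log intensities), complete.
    labels
        class label per sample; exactly two distinct values.
    n_ortho
        number of y-orthogonal components removed before the single
        predictive component (0 gives plain PLS1).
    cv
        ``"loo"``, a fold count, or ``None`` to skip Q2 estimation.
    """
    if X.isna().any().any():
        raise ValueError("OPLS-DA requires a complete matrix (impute first)")
    y, classes = encode_response(labels)
    Xn = X.to_numpy(dtype=float)
    if n_ortho < 0:
        raise ValueError("n_ortho must be >= 0")
    rank = np.linalg.matrix_rank(Xn - Xn.mean(axis=0))
    if n_ortho >= rank:
        raise ValueError(f"n_ortho={n_ortho} must be below the centered rank ({rank})")
    Xc, center, sd = _autoscale(Xn, scale, list(X.columns))
    yc = y - y.mean()
    w, t, p_load, q, W_o, T_o, P_o = _opls_core(Xc, yc, n_ortho)
    flip = _fix_sign(w)
    w, t, p_load, q = w * flip, t * flip, p_load * flip, q * flip
    y_hat = t * q
    r2y = 1.0 - float(np.sum((yc - y_hat) ** 2) / np.sum(yc**2))
    vip = pd.Series(
        _vip_from_components(w[:, None], t[:, None], yc), index=X.columns, name="vip"
    )
    model = OplsModel(
        classes=classes,
        feature_names=list(X.columns),
        w=w,
        t=t,
        p=p_load,
        q=q,
        w_ortho=W_o,
        t_ortho=T_o,
        p_ortho=P_o,
        center=center,
        scale=sd,
        y_mean=float(y.mean()),
        r2y=r2y,
        vip=vip,
    )
    if cv is not None:
        model.q2 = cross_validated_q2(
            X, labels, n_ortho=n_ortho, folds=cv, scale=scale, seed=cv_seed
        )
    return model


def vip_scores(model: OplsModel, include_orthogonal: bool = False) -> pd.Series:
    """Per-feature variable importance in projection.

    By default only the predictive component enters (marker selection should
    reflect class-predictive variation). ``include_orthogonal=True`` adds
    the orthogonal components weighted by their captured X-variance — a
    "total" VIP variant; note the mean-square-1 normalization then holds
    over the combined weighting, not per block.
    """
    if not include_orthogonal or model.n_ortho == 0:
        return model.vip
    # weight orthogonal components by SSX they capture, predictive by SSY
    w_all = np.column_stack([model.w[:, None], model.w_ortho])
    ssx = np.array(
        [model.t @ model.t]
        + [
            (model.t_ortho[:, a] @ model.t_ortho[:, a])
            * (model.p_ortho[:, a] @ model.p_ortho[:, a])
            for a in range(model.n_ortho)
        ]
    )
    wnorm2 = (w_all / np.linalg.norm(w_all, axis=0)) ** 2
    p_feat = w_all.shape[0]
    return pd.Series(
        np.sqrt(p_feat * (wnorm2 @ ssx) / ssx.sum()),
        index=model.feature_names,
        name="vip_total",
    )


def _fold_assignment(
    y: np.ndarray, folds: int, seed: int
) -> list[np.ndarray]:
    """Seeded stratified fold assignment: shuffle within class, deal round-robin."""
    rng = np.random.default_rng(seed)
    members: list[list[int]] = [[] for _ in range(folds)]
    for cls in (1.0, 0.0):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            members[j % folds].append(int(i))
    return [np.array(sorted(m)) for m in members if len(m)]


def cross_validated_q2(
    X: pd.DataFrame,
    labels: Sequence[str],
    n_ortho: int = 1,
    folds: str | int = "loo",
    scale: bool = True,
    seed: int = 0,
) -> float:
    """Cross-validated predictive ability Q2 = 1 - PRESS/SSY.

    Each held-out sample is predicted by a model refit on the remaining
    samples (orthogonal filtering re-estimated per fold). ``folds="loo"``
    leaves one out; an integer gives seeded stratified k-fold. Every
    training fold must retain both classes.
    """
    y, _ = encode_response(labels)
    Xn = X.to_numpy(dtype=float)
    n = len(y)
    if folds == "loo":
        fold_sets = [np.array([i]) for i in range(n)]
    else:
        folds = int(folds)
        if not 2 <= folds <= n:
            raise ValueError(f"folds must be in [2, {n}]")
        fold_sets = _fold_assignment(y, folds, seed)
    press = 0.0
    for test_idx in fold_sets:
        train = np.setdiff1d(np.arange(n), test_idx)
        y_tr = y[train]
        if len(np.unique(y_tr)) < 2:
            raise ValueError("a training fold lost one class entirely")
        X_tr = Xn[train]
        Xc, center, sd = _autoscale(X_tr, scale, list(X.columns))
        yc = y_tr - y_tr.mean()
        w, t, p_load, q, W_o, T_o, P_o = _opls_core(Xc, yc, n_ortho)
        E = (Xn[test_idx] - center) / sd
        for a in range(n_ortho):
            t_o = E @ W_o[:, a]
            E = E - np.outer(t_o, P_o[:, a])
        y_pred = E @ w * q + y_tr.mean()
        press += float(np.sum((y[test_idx] - y_pred) ** 2))
    ssy = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ssy
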