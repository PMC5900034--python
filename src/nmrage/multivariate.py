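"""Multivariate pattern recognition: PCA, BCV rank selection, MMC, CV.

PCA gives the unsupervised view (trajectory plots); bi-cross-validation
(Owen–Perry row×column hold-outs) picks the number of components that
capture systematic rather than noise variance; the maximum margin
criterion (MMC) finds supervised discriminant axes as the top
eigenvectors of ``S_b − S_w``; and leave-mouse-out cross-validation with
a quadratic classifier measures predictive capacity without subject
leakage — all spectra of one animal are withheld together, and every
data-dependent choice (feature selection, PCA, MMC) is refit inside
each fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude element positive (resolves
    eigenvector sign ambiguity deterministically)."""
    W = W.copy()
    for j in range(W.shape[1]):
        k = np.argmax(np.abs(W[:, j]))
        if W[k, j] < 0:
            W[:, j] = -W[:, j]
    return W


@dataclass
class PCAModel:
    mean: np.ndarray
    loadings: np.ndarray  # variables × rank, orthonormal columns
    scores: np.ndarray  # samples × rank
    explained_variance_fraction: np.ndarray
    rank: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.loadings


def pca(X: np.ndarray, rank: int) -> PCAModel:
    """Mean-centered SVD principal component analysis."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if rank > min(n - 1, p):
        raise ValueError(f"rank {rank} exceeds min(samples-1, variables) = {min(n - 1, p)}")
    mean = X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X - mean, full_matrices=False)
    evr = s**2 / max((s**2).sum(), np.finfo(float).tiny)
    V = _fix_signs(Vt[:rank].T)
    scores = (X - mean) @ V
    return PCAModel(
        mean=mean, loadings=V, scores=scores,
        explained_variance_fraction=evr[:rank], rank=rank,
    )


def bcv_rank(
    X: np.ndarray,
    row_folds: int = 2,
    col_folds: int = 2,
    max_rank: int = 10,
    seed: int = 0,
) -> int:
    """Bi-cross-validated rank selection (Owen–Perry hold-out scheme).

    Rows and columns are randomly partitioned into folds; for each
    (row-block, column-block) pair the held-out block ``A`` is predicted
    from the complementary blocks as ``Â_k = B · D_k⁺ · C`` (all blocks
    centered by training-row column means), where ``D_k`` is the rank-k
    truncation of the training block. Returns the k minimizing mean
    squared prediction error; k = 0 (column-mean-only) is allowed and is
    the answer for structureless data.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if row_folds < 2 or col_folds < 2:
        raise ValueError("need at least 2 row folds and 2 column folds")
    if max_rank < 1:
        raise ValueError("max_rank must be >= 1")
    rng = np.random.default_rng(seed)
    row_assign = rng.permuted(np.arange(n) % row_folds)
    col_assign = rng.permuted(np.arange(p) % col_folds)

    min_d = min(n - max(np.bincount(row_assign)), p - max(np.bincount(col_assign)))
    if max_rank > min_d - 1:
        warnings.warn(
            f"max_rank {max_rank} too large for fold blocks; reduced to {min_d - 1}"
        )
        max_rank = max(min_d - 1, 1)

    errs = np.zeros(max_rank + 1)
    for rf in range(row_folds):
        hr = row_assign == rf
        for cf in range(col_folds):
            hc = col_assign == cf
            A = X[np.ix_(hr, hc)]
            B = X[np.ix_(hr, ~hc)]
            C = X[np.ix_(~hr, hc)]
            D = X[np.ix_(~hr, ~hc)]
            mu_keep = D.mean(axis=0)  # training-row means of kept cols
            mu_hold = C.mean(axis=0)  # training-row means of held cols
            Bc, Cc, Dc = B - mu_keep, C - mu_hold, D - mu_keep
            U, s, Vt = np.linalg.svd(Dc, full_matrices=False)
            errs[0] += ((A - mu_hold) ** 2).mean()
            P = Bc @ Vt.T  # held rows × r
            Q = U.T @ Cc  # r × held cols
            pred = np.zeros_like(A)
            for k in range(1, max_rank + 1):
                if k <= s.size and s[k - 1] > 1e-12 * s[0]:
                    pred = pred + np.outer(P[:, k - 1] / s[k - 1], Q[k - 1])
                errs[k] += ((A - mu_hold - pred) ** 2).mean()
    return int(np.argmin(errs))


@dataclass
class MMCModel:
    """Maximum margin criterion discriminant model.

    Discriminant loadings are the top eigenvectors of ``S_b − S_w``
    (between-class minus within-class scatter, both normalized by the
    total sample count)."""

    S_b: np.ndarray
    S_w: np.ndarray
    loadings: np.ndarray  # features × n_components
    eigenvalues: np.ndarray
    scores: np.ndarray
    classes: np.ndarray
    mean: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.loadings


def _scatter_matrices(X: np.ndarray, y: np.ndarray):
    classes = np.unique(y)
    n, p = X.shape
    mu = X.mean(axis=0)
    S_b = np.zeros((p, p))
    S_w = np.zeros((p, p))
    for c in classes:
        Xc = X[y == c]
        if Xc.shape[0] < 2:
            raise ValueError(
                f"class {c!r} has {Xc.shape[0]} sample(s); within-class "
                "scatter needs at least 2 per class"
            )
        mc = Xc.mean(axis=0)
        d = mc - mu
        S_b += Xc.shape[0] * np.outer(d, d)
        R = Xc - mc
        S_w += R.T @ R
    return S_b / n, S_w / n, classes, mu


def mmc(X: np.ndarray, labels, n_components: int | None = None) -> MMCModel:
    """Fit an MMC discriminant model; default output dimension is
    ``n_classes - 1`` (the informative subspace of ``S_b``)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.size:
        raise ValueError("labels length must match sample count")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("MMC needs at least 2 classes")
    S_b, S_w, classes, mu = _scatter_matrices(X, y)
    k = n_components or (classes.size - 1)
    if k > X.shape[1]:
        raise ValueError(f"n_components {k} exceeds feature count {X.shape[1]}")
    evals, evecs = np.linalg.eigh(S_b - S_w)
    order = np.argsort(evals)[::-1][:k]
    W = _fix_signs(evecs[:, order])
    return MMCModel(
        S_b=S_b, S_w=S_w, loadings=W, eigenvalues=evals[order],
        scores=(X - mu) @ W, classes=classes, mean=mu,
    )


# -- quadratic classifier ---------------------------------------------

def _qda_fit(Z: np.ndarray, y: np.ndarray, shrinkage: float):
    params = {}
    for c in np.unique(y):
        Zc = Z[y == c]
        mu = Zc.mean(axis=0)
        cov = np.cov(Zc, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        cov = (1.0 - shrinkage) * cov + shrinkage * np.diag(np.diag(cov))
        # tiny ridge keeps log-det finite for degenerate folds
        cov += 1e-10 * np.eye(cov.shape[0]) * max(np.trace(cov), 1.0)
        params[c] = (mu, np.linalg.inv(cov), np.linalg.slogdet(cov)[1])
    return params


def _qda_predict(Z: np.ndarray, params) -> np.ndarray:
    classes = sorted(params)
    d = np.empty((Z.shape[0], len(classes)))
    for j, c in enumerate(classes):
        mu, prec, logdet = params[c]
        R = Z - mu
        d[:, j] = np.einsum("ij,jk,ik->i", R, prec, R) + logdet
    return np.asarray(classes)[np.argmin(d, axis=1)]


@dataclass
class CVReport:
    confusion: pd.DataFrame  # true × predicted counts
    accuracy: float
    predicted_variance: float
    assignments: pd.DataFrame  # sample_id, mouse_id, true, predicted
    warnings: list = field(default_factory=list)


@dataclass
class CVPipelineSpec:
    """What is refit inside every fold of leave-mouse-out CV."""

    select_features: bool = False  # one-way ANOVA p<0.05 on training folds
    select_alpha: float = 0.05
    max_rank: int = 10  # PCA rank cap before MMC
    n_components: int | None = None  # MMC axes; default classes-1
    shrinkage: float = 0.1  # QDA covariance shrinkage toward its diagonal


def _anova_select(X: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    from nmrage.univariate import anova_f_arrays

    _, p, _ = anova_f_arrays(X, y)
    mask = p < alpha
    if mask.sum() < 2:  # degenerate selection: keep everything
        mask = np.ones(X.shape[1], dtype=bool)
    return mask


def leave_mouse_out_cv(
    X: np.ndarray,
    labels,
    mouse_ids,
    spec: CVPipelineSpec | None = None,
) -> CVReport:
    """Leave-mouse-out cross-validation with quadratic classification.

    Folds are the unique mice. Per fold, the training mice are used to
    (optionally) select features, fit PCA (rank capped at
    ``n_train - n_classes``), fit MMC on the PCA scores, and estimate
    per-class Gaussians in discriminant space; held-out spectra are
    projected and assigned to the class with the smallest quadratic
    discriminant distance ``(z−μ_c)ᵀ Σ_c⁻¹ (z−μ_c) + ln det Σ_c``.
    Predicted variance is 1 − (held-out residual SS after projection onto
    the training discriminant space) / (held-out total centered SS).
    """
    spec = spec or CVPipelineSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    mice_arr = np.asarray(mouse_ids)
    if not (X.shape[0] == y.size == mice_arr.size):
        raise ValueError("X, labels and mouse_ids must agree in length")
    classes = np.unique(y)
    for c in classes:
        if np.unique(mice_arr[y == c]).size < 2:
            raise ValueError(f"class {c!r} has fewer than 2 mice")

    fold_mice = np.unique(mice_arr)
    notes = []
    preds = np.empty(X.shape[0], dtype=y.dtype)
    done = np.zeros(X.shape[0], dtype=bool)
    rss_total = 0.0
    tss_total = 0.0
    for m in fold_mice:
        test = mice_arr == m
        train = ~test
        ytr = y[train]
        if np.unique(ytr).size < classes.size:
            notes.append(f"fold {m!r} skipped: a class is absent from training")
            continue
        Xtr, Xte = X[train], X[test]
        if spec.select_features:
            mask = _anova_select(Xtr, ytr, spec.select_alpha)
        else:
            mask = np.ones(X.shape[1], dtype=bool)
        rank = min(
            spec.max_rank, Xtr.shape[0] - classes.size, int(mask.sum()),
        )
        rank = max(rank, 1)
        pc = pca(Xtr[:, mask], rank)
        model = mmc(pc.scores, ytr, n_components=spec.n_components)
        Ztr = model.scores
        Zte = model.transform(pc.transform(Xte[:, mask]))
        params = _qda_fit(Ztr, ytr, spec.shrinkage)
        preds[test] = _qda_predict(Zte, params)
        done[test] = True
        # discriminant subspace in (selected) feature space is orthonormal:
        # PCA loadings orthonormal, MMC loadings orthonormal
        M = pc.loadings @ model.loadings
        R = Xte[:, mask] - Xtr[:, mask].mean(axis=0)
        proj = (R @ M) @ M.T
        rss_total += ((R - proj) ** 2).sum()
        tss_total += (R**2).sum()

    if not done.any():
        raise ValueError("every fold was skipped; cannot build a CV report")
    conf = pd.crosstab(
        pd.Series(y[done], name="true"),
        pd.Series(preds[done], name="predicted"),
        dropna=False,
    ).reindex(index=classes, columns=classes, fill_value=0)
    acc = float(np.trace(conf.to_numpy()) / conf.to_numpy().sum())
    pv = float(1.0 - rss_total / tss_total) if tss_total > 0 else float("nan")
    assignments = pd.DataFrame({
        "mouse_id": mice_arr[done],
        "true": y[done],
        "predicted": preds[done],
    })
    return CVReport(
        confusion=conf, accuracy=acc, predicted_variance=pv,
        assignments=assignments, warnings=notes,
    )
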