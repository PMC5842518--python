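"""Multilinear PCA for matrix-valued samples, with discriminability ranking.

Each sample is a 2nd-order tensor (a frames x fingerprint-bits matrix).
:class:`MultilinearPCA` finds per-mode orthonormal projection matrices
U1 (frames mode) and U2 (fingerprint mode) maximizing the total tensor
scatter sum_m ||Y_m||_F^2 of the projected samples Y_m = U1' X_m U2, by
alternating eigendecompositions of the mode-wise partial scatter matrices.

:class:`DiscriminantFeatureSelector` then ranks the P1 x P2 projected
entries by the class discriminability

    Gamma(p) = sum_c N_c (mean_c(p) - mean(p))^2
               / sum_m (Y_m(p) - mean_{class(m)}(p))^2

(between-class over within-class scatter, per entry) and keeps the top H
entries as the feature vector of each sample.

Both are scikit-learn style estimators (``fit`` / ``transform``,
``get_params`` / ``set_params``, fitted attributes with trailing
underscores); the module-level functions are thin wrappers.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.linalg import eigh
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "MultilinearPCA", "DiscriminantFeatureSelector",
    "fit_mpca", "project", "discriminability", "select_features",
]


def _as_tensor(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError(
            f"expected a 3-D array (samples, frames, bits), got shape {X.shape}"
        )
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    return X


def _top_eigvecs(S: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Leading p eigenvectors/values of a symmetric PSD matrix, descending."""
    vals, vecs = eigh(S)
    order = np.argsort(vals)[::-1]
    return vecs[:, order[:p]], np.maximum(vals[order], 0.0)


def _mode_scatter(X: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n total scatter matrix sum_m X_m X_m' (mode 1) or X_m' X_m (mode 2)."""
    if mode == 1:
        return np.einsum("mij,mkj->ik", X, X, optimize=True)
    return np.einsum("mij,mik->jk", X, X, optimize=True)


class MultilinearPCA(BaseEstimator, TransformerMixin):
    """Multilinear PCA on (samples, frames, bits) tensors.

    Parameters
    ----------
    var_kept : float, default 0.97
        Fraction of per-mode eigenvalue mass retained when choosing the mode
        dimensions P1, P2 at initialization.  Ignored if ``n_components`` is
        given.
    n_components : tuple (P1, P2), optional
        Explicit retained dimensions per mode.
    max_iter : int, default 20
        Maximum alternating iterations.
    tol : float, default 1e-6
        Relative change in total projected scatter at which iteration stops.
    center : bool, default True
        Subtract the sample-mean matrix before fitting.  Input that is not
        already centered triggers a warning and is auto-centered.

    Attributes
    ----------
    U1_, U2_ : orthonormal projection matrices (I1 x P1, I2 x P2).
    mean_ : sample mean matrix used for centering (zeros if data arrived
        centered).
    n_components_ : (P1, P2) actually retained.
    scatter_ratio_ : projected / total scatter after the final iteration.
    mode_energy_ : per-mode eigenvalue mass fraction retained at init.
    scatter_history_ : total projected scatter after each iteration
        (non-decreasing).
    """

    def __init__(self, var_kept: float = 0.97,
                 n_components: tuple[int, int] | None = None,
                 max_iter: int = 20, tol: float = 1e-6, center: bool = True):
        self.var_kept = var_kept
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.center = center

    def fit(self, X, y=None):
        X = _as_tensor(X)
        M, I1, I2 = X.shape
        if self.n_components is None and not (0.0 < self.var_kept <= 1.0):
            raise ValueError("var_kept must lie in (0, 1]")

        mean = X.mean(axis=0)
        if self.center:
            if np.abs(mean).max() > 1e-9:
                warnings.warn(
                    "input samples are not centered; auto-centering",
                    stacklevel=2,
                )
            self.mean_ = mean
            X = X - mean
        else:
            self.mean_ = np.zeros((I1, I2))

        # Initialization: full-projection truncation — eigenvectors of the
        # mode-n total scatter of the (centered) samples.
        S1 = _mode_scatter(X, 1)
        S2 = _mode_scatter(X, 2)
        V1, w1 = _top_eigvecs(S1, I1)
        V2, w2 = _top_eigvecs(S2, I2)

        if self.n_components is not None:
            P1, P2 = self.n_components
            if not (1 <= P1 <= I1 and 1 <= P2 <= I2):
                raise ValueError(
                    f"n_components {self.n_components} out of range for "
                    f"sample shape ({I1}, {I2})"
                )
        else:
            P1 = self._pick_dim(w1)
            P2 = self._pick_dim(w2)
        self.mode_energy_ = (
            self._mass(w1, P1),
            self._mass(w2, P2),
        )
        U1, U2 = V1[:, :P1], V2[:, :P2]

        total = float(np.sum(X * X))
        history: list[float] = []
        prev = -np.inf
        for _ in range(self.max_iter):
            # U1 <- top-P1 eigenvectors of sum_m X_m U2 U2' X_m'
            XU2 = X @ U2                      # (M, I1, P2)
            U1, _ = _top_eigvecs(np.einsum("mip,mjp->ij", XU2, XU2, optimize=True), P1)
            # U2 <- top-P2 eigenvectors of sum_m X_m' U1 U1' X_m
            XtU1 = np.einsum("mij,ip->mjp", X, U1, optimize=True)   # (M, I2, P1)
            U2, _ = _top_eigvecs(np.einsum("mjp,mkp->jk", XtU1, XtU1, optimize=True), P2)
            Y = np.einsum("ip,mij,jq->mpq", U1, X, U2, optimize=True)
            scatter = float(np.sum(Y * Y))
            history.append(scatter)
            if scatter - prev < self.tol * max(scatter, 1e-30):
                break
            prev = scatter

        self.U1_, self.U2_ = U1, U2
        self.n_components_ = (P1, P2)
        self.scatter_history_ = np.asarray(history)
        self.scatter_ratio_ = history[-1] / total if total > 0 else 1.0
        self.n_features_in_ = I1 * I2
        return self

    def _pick_dim(self, w: np.ndarray) -> int:
        mass = np.cumsum(w) / max(w.sum(), 1e-300)
        return int(np.searchsorted(mass, self.var_kept - 1e-12) + 1)

    @staticmethod
    def _mass(w: np.ndarray, p: int) -> float:
        s = w.sum()
        return float(w[:p].sum() / s) if s > 0 else 1.0

    def transform(self, X) -> np.ndarray:
        """Project samples: Y_m = U1' (X_m - mean) U2, shape (M, P1, P2)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "U1_")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        if single:
            X = X[None]
        if X.shape[1:] != self.mean_.shape:
            raise ValueError(
                f"sample shape {X.shape[1:]} does not match fitted shape "
                f"{self.mean_.shape}"
            )
        Y = np.einsum("ip,mij,jq->mpq", self.U1_, X - self.mean_, self.U2_, optimize=True)
        return Y[0] if single else Y

    def inverse_transform(self, Y) -> np.ndarray:
        Y = np.asarray(Y, dtype=float)
        single = Y.ndim == 2
        if single:
            Y = Y[None]
        X = np.einsum("ip,mpq,jq->mij", self.U1_, Y, self.U2_, optimize=True) + self.mean_
        return X[0] if single else X


class DiscriminantFeatureSelector(BaseEstimator, TransformerMixin):
    """Rank projected-tensor entries by class discriminability, keep top H.

    ``fit`` takes projected samples (M, P1, P2) and class labels; ``transform``
    returns (M, H) feature vectors read in descending-Gamma order.  Entries
    with zero within-class scatter but nonzero between-class scatter get
    Gamma = +inf (rank first); entries constant across all samples get
    Gamma = 0 (rank last).  Ties break by ascending (p1, p2) position.
    """

    def __init__(self, H: int | None = None):
        self.H = H

    def fit(self, Y, y):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 2:
            Y = Y[:, :, None]
        if Y.ndim != 3:
            raise ValueError("expected projected samples of shape (M, P1, P2)")
        y = np.asarray(y)
        if len(y) != Y.shape[0]:
            raise ValueError("one label per sample required")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("class discriminability needs at least two classes")

        grand = Y.mean(axis=0)
        between = np.zeros(Y.shape[1:])
        within = np.zeros(Y.shape[1:])
        for c in classes:
            Yc = Y[y == c]
            mc = Yc.mean(axis=0)
            between += len(Yc) * (mc - grand) ** 2
            within += ((Yc - mc) ** 2).sum(axis=0)

        with np.errstate(divide="ignore", invalid="ignore"):
            gamma = between / within
        gamma[(within == 0) & (between > 0)] = np.inf
        gamma[(within == 0) & (between == 0)] = 0.0

        self.gamma_ = gamma
        flat = gamma.ravel()
        # stable sort on -gamma gives descending gamma with lexicographic
        # (p1, p2) tie-break; +inf sorts first, exact zeros last by value
        self.order_ = np.argsort(-flat, kind="stable")
        self.classes_ = classes
        self.n_features_in_ = flat.size
        return self

    def transform(self, Y) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "order_")
        Y = np.asarray(Y, dtype=float)
        flat = Y.reshape(Y.shape[0], -1) if Y.ndim == 3 else np.atleast_2d(Y)
        if flat.shape[1] != len(self.order_):
            raise ValueError(
                f"samples have {flat.shape[1]} entries, selector was fitted "
                f"on {len(self.order_)}"
            )
        H = self.H if self.H is not None else len(self.order_)
        if not (1 <= H <= len(self.order_)):
            raise ValueError(f"H={H} out of range [1, {len(self.order_)}]")
        return flat[:, self.order_[:H]]


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------

def fit_mpca(samples, var_kept: float = 0.97,
             n_components: tuple[int, int] | None = None,
             max_iter: int = 20, tol: float = 1e-6) -> MultilinearPCA:
    """Fit :class:`MultilinearPCA` on already-centered matrix samples."""
    return MultilinearPCA(
        var_kept=var_kept, n_components=n_components,
        max_iter=max_iter, tol=tol,
    ).fit(np.asarray(samples))


def project(model: MultilinearPCA, sample) -> np.ndarray:
    return model.transform(sample)


def discriminability(projected, labels) -> np.ndarray:
    """Per-entry class discriminability Gamma of projected samples."""
    sel = DiscriminantFeatureSelector().fit(projected, labels)
    return sel.gamma_


def select_features(projected, labels, H: int) -> np.ndarray:
    """Top-H feature matrix (M, H) in descending-Gamma order."""
    sel = DiscriminantFeatureSelector(H=H).fit(projected, labels)
    return sel.transform(np.asarray(projected))
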