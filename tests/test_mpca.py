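"""Multilinear PCA and discriminability-ranked feature selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tkisense.mpca import (DiscriminantFeatureSelector, MultilinearPCA,
                           discriminability, fit_mpca, project,
                           select_features)


def _centered(rng, m, i1, i2):
    X = rng.normal(size=(m, i1, i2))
    return X - X.mean(axis=0)


# ----------------------------------------------------------------- fitting

def test_full_projection_preserves_scatter(rng):
    """With P_n = I_n the Frobenius scatter is exactly preserved."""
    X = _centered(rng, 8, 5, 7)
    model = MultilinearPCA(n_components=(5, 7), center=False).fit(X)
    Y = model.transform(X)
    assert np.isclose((Y ** 2).sum(), (X ** 2).sum(), rtol=1e-10)
    assert model.scatter_ratio_ == pytest.approx(1.0)


def test_scatter_monotone_and_orthonormal(rng):
    X = _centered(rng, 10, 6, 9)
    model = MultilinearPCA(n_components=(3, 4), center=False, tol=0).fit(X)
    hist = model.scatter_history_
    assert np.all(np.diff(hist) >= -1e-8 * hist[-1])
    for U in (model.U1_, model.U2_):
        assert np.abs(U.T @ U - np.eye(U.shape[1])).max() < 1e-8


def test_pca_limit_equivalence(rng):
    """For 1 x N samples the retained scatter equals classic PCA variance."""
    X = _centered(rng, 15, 1, 8)
    model = MultilinearPCA(n_components=(1, 3), center=False).fit(X)
    S = np.einsum("mj,mk->jk", X[:, 0, :], X[:, 0, :])
    eigvals = np.sort(np.linalg.eigvalsh(S))[::-1]
    assert model.scatter_history_[-1] == pytest.approx(
        eigvals[:3].sum(), rel=1e-6
    )
    # projected coordinates span the same subspace as the top eigenvectors
    Y = model.transform(X)
    assert np.isclose((Y ** 2).sum(), eigvals[:3].sum(), rtol=1e-6)


def test_rank11_samples_fully_captured(rng):
    """Samples in a rank-(1,1) subspace are captured exactly at P=(1,1)."""
    u = rng.normal(size=4)
    v = rng.normal(size=6)
    coef = rng.normal(size=10)
    coef -= coef.mean()
    X = coef[:, None, None] * np.outer(u, v)
    model = MultilinearPCA(n_components=(1, 1), center=False).fit(X)
    assert model.scatter_ratio_ == pytest.approx(1.0)


def test_var_kept_selects_dimensions(rng):
    X = _centered(rng, 12, 5, 6)
    model = MultilinearPCA(var_kept=1.0, center=False).fit(X)
    assert model.n_components_ == (5, 6)
    small = MultilinearPCA(var_kept=0.5, center=False).fit(X)
    assert small.n_components_[0] <= 5 and small.n_components_[1] <= 6
    assert all(e >= 0.5 for e in small.mode_energy_)


def test_auto_center_warns(rng):
    X = rng.normal(size=(6, 3, 4)) + 5.0
    with pytest.warns(UserWarning, match="not centered"):
        model = MultilinearPCA(n_components=(3, 4)).fit(X)
    assert np.abs(model.mean_ - X.mean(axis=0)).max() < 1e-12


def test_fit_errors():
    with pytest.raises(ValueError, match="two samples"):
        MultilinearPCA().fit(np.zeros((1, 3, 3)))
    with pytest.raises(ValueError, match="3-D"):
        MultilinearPCA().fit(np.zeros((4, 3)))
    with pytest.raises(ValueError, match="out of range"):
        MultilinearPCA(n_components=(9, 1), center=False).fit(
            np.zeros((4, 3, 3))
        )


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(3, 8), st.integers(2, 5), st.integers(2, 6),
       st.integers(0, 2 ** 31 - 1))
def test_projection_never_exceeds_total_scatter(m, i1, i2, seed):
    rng = np.random.default_rng(seed)
    X = _centered(rng, m, i1, i2)
    p1 = rng.integers(1, i1 + 1)
    p2 = rng.integers(1, i2 + 1)
    model = MultilinearPCA(n_components=(int(p1), int(p2)),
                           center=False).fit(X)
    assert model.scatter_history_[-1] <= (X ** 2).sum() * (1 + 1e-10)
    assert np.all(np.diff(model.scatter_history_)
                  >= -1e-8 * max(model.scatter_history_[-1], 1e-12))


# -------------------------------------------------------------- projection

def test_project_zero_and_idempotence(rng):
    X = _centered(rng, 6, 4, 5)
    model = MultilinearPCA(n_components=(2, 3), center=False).fit(X)
    assert np.allclose(model.transform(np.zeros((4, 5))), 0)
    inside = model.inverse_transform(model.transform(X[0]))
    again = model.inverse_transform(model.transform(inside))
    assert np.abs(inside - again).max() < 1e-8


def test_project_hand_computed_example():
    """3x3 integer sample against hand-chosen orthonormal projections."""
    sample = np.array([[1.0, 2.0, 3.0],
                       [4.0, 5.0, 6.0],
                       [7.0, 8.0, 9.0]])
    model = MultilinearPCA(n_components=(2, 2), center=False)
    # swap rows 1/2, keep row 3; average/difference of columns 1 and 3
    model.U1_ = np.array([[0.0, 1.0], [1.0, 0.0], [0.0, 0.0]])
    r = 1 / np.sqrt(2)
    model.U2_ = np.array([[r, r], [0.0, 0.0], [r, -r]])
    model.mean_ = np.zeros((3, 3))
    expected = np.array([[r * 10.0, -r * 2.0],
                         [r * 4.0, -r * 2.0]])
    np.testing.assert_allclose(model.transform(sample), expected, atol=1e-12)


def test_project_shape_mismatch(rng):
    X = _centered(rng, 5, 3, 4)
    model = MultilinearPCA(n_components=(2, 2), center=False).fit(X)
    with pytest.raises(ValueError, match="shape"):
        model.transform(np.zeros((4, 3)))


# --------------------------------------------------------- discriminability

def test_gamma_hand_example():
    """Two classes with values {0,0} and {1,3}: Gamma = 4/2 = 2."""
    Y = np.array([0.0, 0.0, 1.0, 3.0]).reshape(4, 1, 1)
    labels = np.array(["a", "a", "b", "b"])
    assert discriminability(Y, labels)[0, 0] == pytest.approx(2.0)


def test_gamma_degenerate_entries():
    # entry 0: constant within class, differs between -> +inf, ranked first
    # entry 1: identical everywhere -> 0, ranked last
    # entry 2: ordinary finite value
    Y = np.array([
        [[1.0, 5.0, 0.1]],
        [[1.0, 5.0, -0.2]],
        [[2.0, 5.0, 1.1]],
        [[2.0, 5.0, 0.9]],
    ])
    labels = np.array(["a", "a", "b", "b"])
    sel = DiscriminantFeatureSelector().fit(Y, labels)
    gamma = sel.gamma_.ravel()
    assert np.isinf(gamma[0]) and gamma[1] == 0.0
    assert sel.order_[0] == 0 and sel.order_[-1] == 1


def test_gamma_requires_two_classes():
    Y = np.zeros((3, 2, 2))
    with pytest.raises(ValueError, match="two classes"):
        discriminability(Y, ["a", "a", "a"])


def _gamma_bruteforce(Y, labels):
    """Independent loop implementation of the discriminability ratio."""
    M, P1, P2 = Y.shape
    classes = sorted(set(labels))
    out = np.zeros((P1, P2))
    for p1 in range(P1):
        for p2 in range(P2):
            vals = Y[:, p1, p2]
            grand = sum(vals) / M
            num = 0.0
            den = 0.0
            for c in classes:
                cv = [v for v, l in zip(vals, labels) if l == c]
                mc = sum(cv) / len(cv)
                num += len(cv) * (mc - grand) ** 2
                den += sum((v - mc) ** 2 for v in cv)
            if den == 0:
                out[p1, p2] = np.inf if num > 0 else 0.0
            else:
                out[p1, p2] = num / den
    return out


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(4, 12), st.integers(1, 3), st.integers(1, 3),
       st.integers(2, 3), st.integers(0, 2 ** 31 - 1))
def test_gamma_matches_bruteforce(m, p1, p2, n_classes, seed):
    rng = np.random.default_rng(seed)
    labels = np.array([f"c{i % n_classes}" for i in range(m)])
    Y = rng.normal(size=(m, p1, p2))
    got = discriminability(Y, labels)
    want = _gamma_bruteforce(Y, labels)
    finite = np.isfinite(want)
    np.testing.assert_allclose(got[finite], want[finite], rtol=1e-10)
    np.testing.assert_array_equal(np.isinf(got), np.isinf(want))


def test_sample_permutation_invariance(rng):
    """Reordering samples (with labels) changes neither Gamma nor features."""
    Y = rng.normal(size=(9, 2, 3))
    labels = np.array(["a", "b", "c"] * 3)
    perm = rng.permutation(9)
    g1 = discriminability(Y, labels)
    g2 = discriminability(Y[perm], labels[perm])
    np.testing.assert_allclose(g1, g2)
    f1 = select_features(Y, labels, H=4)
    f2 = select_features(Y[perm], labels[perm], H=4)
    np.testing.assert_allclose(f1[perm], f2)


# ----------------------------------------------------------- select features

def test_select_features_full_is_permutation(rng):
    Y = rng.normal(size=(6, 2, 3))
    labels = ["a", "a", "a", "b", "b", "b"]
    feats = select_features(Y, labels, H=6)
    flat = Y.reshape(6, -1)
    for m in range(6):
        assert sorted(feats[m]) == pytest.approx(sorted(flat[m]))


def test_select_features_top3_are_largest_gamma(rng):
    Y = rng.normal(size=(8, 3, 3))
    labels = ["a", "b"] * 4
    gamma = discriminability(Y, labels).ravel()
    top3 = np.argsort(-gamma, kind="stable")[:3]
    feats = select_features(Y, labels, H=3)
    np.testing.assert_allclose(feats, Y.reshape(8, -1)[:, top3])


def test_select_features_range_errors(rng):
    Y = rng.normal(size=(4, 2, 2))
    labels = ["a", "a", "b", "b"]
    for H in (0, 5):
        with pytest.raises(ValueError, match="out of range"):
            select_features(Y, labels, H=H)


def test_tie_break_is_lexicographic():
    """Equal-Gamma entries keep ascending (p1, p2) order."""
    Y = np.zeros((4, 2, 2))
    Y[2:, :, :] = 1.0          # every entry identically discriminative
    labels = ["a", "a", "b", "b"]
    sel = DiscriminantFeatureSelector().fit(Y, labels)
    np.testing.assert_array_equal(sel.order_, [0, 1, 2, 3])


def test_sklearn_param_interface():
    model = MultilinearPCA(var_kept=0.9)
    assert model.get_params()["var_kept"] == 0.9
    model.set_params(max_iter=5)
    assert model.max_iter == 5
    sel = DiscriminantFeatureSelector(H=4)
    assert sel.get_params() == {"H": 4}


def test_functional_wrappers_match_estimators(rng):
    X = _centered(rng, 7, 4, 5)
    model = fit_mpca(X, n_components=(2, 2))
    Y = project(model, X)
    assert Y.shape == (7, 2, 2)
    np.testing.assert_allclose(Y, model.transform(X))
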