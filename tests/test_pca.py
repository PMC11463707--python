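"""Eigen-wavefront basis: fitting, projection, truncation, composition."""

import numpy as np
import pytest

from accowave.pca import (
    cumulative_variance_table,
    eigenvector_composition,
    fit_basis,
    project,
    reconstruct,
)
from accowave.zernike import MODES, N_PARAMETERS


def toy_two_column(n=40, seed=3):
    """Independent columns with sample variances exactly 9 and 1."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    a -= a.mean()
    b -= b.mean()
    b -= a * (a @ b) / (a @ a)  # exactly decorrelate
    a *= 3.0 / a.std(ddof=1)
    b /= b.std(ddof=1)
    return np.column_stack([a, b])


def test_toy_eigenvalue_fractions():
    X = toy_two_column()
    basis = fit_basis(X, cutoff=1.0)
    np.testing.assert_allclose(basis.eigenvalues, [9.0, 1.0], atol=1e-10)
    table = cumulative_variance_table(basis)
    np.testing.assert_allclose(table["cumulative_variance_pct"], [90.0, 100.0], atol=1e-8)
    # 90% cutoff retains exactly the first eigenvector
    k1 = fit_basis(X, cutoff=0.9)
    assert k1.k == 1
    np.testing.assert_allclose(
        cumulative_variance_table(k1)["cumulative_variance_pct"], [90.0], atol=1e-8
    )


def test_degenerate_and_invalid_inputs():
    with pytest.raises(ValueError):
        fit_basis(np.ones((5, 4)))  # constant rows: zero variance
    with pytest.raises(ValueError):
        fit_basis(np.ones((1, 4)))
    with pytest.raises(ValueError):
        fit_basis(np.full((3, 4), np.nan))


def test_full_cutoff_retains_rank(rng):
    X = rng.normal(size=(10, 6))
    basis = fit_basis(X, cutoff=1.0)
    assert basis.k == min(10 - 1, 6)


def test_orthonormality_and_variance_conservation(rng):
    X = rng.normal(size=(50, 12)) @ np.diag(np.linspace(3, 0.1, 12))
    basis = fit_basis(X, cutoff=1.0)
    gram = basis.eigenvectors.T @ basis.eigenvectors
    np.testing.assert_allclose(gram, np.eye(basis.k), atol=1e-10)
    trace = np.trace(np.cov(X, rowvar=False, ddof=1))
    assert basis.total_variance == pytest.approx(trace, abs=1e-8)


def test_agrees_with_svd_oracle(rng):
    """Brute-force SVD of the centred matrix is an independent route to
    the same eigenvalues/eigenvectors (up to sign)."""
    X = rng.normal(size=(10, 6))
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigs = s**2 / (10 - 1)
    basis = fit_basis(X, cutoff=1.0)
    np.testing.assert_allclose(basis.eigenvalues, eigs[: basis.k], atol=1e-10)
    for j in range(basis.k):
        dot = abs(Vt[j] @ basis.eigenvectors[:, j])
        assert dot == pytest.approx(1.0, abs=1e-10)


def test_projection_reconstruction_cycle(rng):
    X = rng.normal(size=(30, 8))
    basis = fit_basis(X, cutoff=1.0)
    np.testing.assert_allclose(project(basis.mean, basis), np.zeros(basis.k), atol=1e-10)
    np.testing.assert_allclose(reconstruct(project(X, basis), basis), X, atol=1e-10)
    with pytest.raises(ValueError):
        project(np.zeros(7), basis)
    with pytest.raises(ValueError):
        reconstruct(np.zeros(basis.k + 1), basis)


def test_truncated_reconstruction_residual_bound(rng):
    X = rng.normal(size=(60, 10)) @ np.diag(np.linspace(2, 0.05, 10))
    cutoff = 0.95
    basis = fit_basis(X, cutoff=cutoff)
    resid = X - reconstruct(project(X, basis), basis)
    mean_sq = np.sum(resid**2, axis=1).sum() / (X.shape[0] - 1)
    assert mean_sq <= (1 - cutoff) * basis.total_variance + 1e-10


def test_scores_are_uncorrelated(default_run):
    scores = project(default_run["cohort"].data, default_run["basis"])
    C = np.cov(scores, rowvar=False, ddof=1)
    d = np.sqrt(np.diag(C))
    corr = C / np.outer(d, d)
    off = corr - np.diag(np.diag(corr))
    assert np.abs(off).max() < 1e-8


def test_retained_k_bounds(default_run):
    basis = default_run["basis"]
    assert basis.k <= min(191 - 1, N_PARAMETERS)
    assert basis.cumulative_variance[-1] >= basis.cutoff - 1e-12


def test_composition_pure_and_tied_loadings():
    # hand-built basis: eigenvector 1 loads only c(2,0), eigenvector 2
    # loads two modes equally
    E = np.zeros((N_PARAMETERS, 2))
    j20 = MODES.index((2, 0))
    j22 = MODES.index((2, 2))
    for d in range(6):
        E[d * 25 + j20, 0] = 1.0
        E[d * 25 + j20, 1] = 1.0
        E[d * 25 + j22, 1] = 1.0
    E /= np.linalg.norm(E, axis=0)
    from accowave.pca import EigenBasis

    basis = EigenBasis(
        mean=np.zeros(N_PARAMETERS),
        eigenvectors=E,
        eigenvalues=np.array([2.0, 1.0]),
        cumulative_variance=np.array([2 / 3, 1.0]),
        total_variance=3.0,
        cutoff=1.0,
    )
    comp1 = eigenvector_composition(basis, 1)
    assert comp1.attrs["fundamental_mode"] == (2, 0)
    assert comp1.attrs["fundamental_share_pct"] == pytest.approx(100.0)
    comp2 = eigenvector_composition(basis, 2)
    assert comp2.attrs["fundamental_share_pct"] == pytest.approx(50.0)
    assert comp2.attrs["fundamental_mode"] == (2, 0)  # tie broken by single index
    assert comp2.attrs["dominant"]  # 50% share is above the 40% threshold


def test_leading_eigenvectors_dominated_by_low_order_modes(default_run):
    """On the defocus-dominated synthetic cohort the first eigenvectors
    have a fundamental component above 40%, like clinical eigen-wavefronts."""
    basis = default_run["basis"]
    for k in range(1, 5):
        comp = eigenvector_composition(basis, k)
        assert comp.attrs["fundamental_share_pct"] > 40.0
    comp1 = eigenvector_composition(basis, 1)
    assert comp1.attrs["fundamental_mode"] == (2, 0)  # defocus leads


def test_cumulative_table_with_cohort_limits(default_run):
    basis = default_run["basis"]
    table = cumulative_variance_table(basis, default_run["cohort"].data)
    assert table["cumulative_variance_pct"].is_monotonic_increasing
    assert table["cumulative_variance_pct"].iloc[-1] >= basis.cutoff * 100 - 1e-9
    assert (table["max_um"] >= table["min_um"]).all()
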