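"""Channel weight coefficients: closed forms, oracles, and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seizelect.cwc import (DegenerateWindowError, channel_weights,
                           channel_weights_svd, cwc_series, pca_loadings,
                           weighted_loadings)

SQRT2 = np.sqrt(2.0)


def _two_column_window(rng, n=256):
    x = rng.standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=1)
    return x


def test_identical_columns_closed_form(rng):
    """Two identical unit-variance columns: covariance [[1,1],[1,1]] has
    eigenvalues (2, 0) and first eigenvector (1,1)/sqrt(2), so
    CWC = 2 * 1/sqrt(2) = sqrt(2) for both channels."""
    x = _two_column_window(rng)
    X = np.column_stack([x, x])
    dec = pca_loadings(X)
    np.testing.assert_allclose(dec.eigenvalues, [2.0, 0.0], atol=1e-9)
    np.testing.assert_allclose(np.abs(dec.loadings[:, 0]), [1 / SQRT2, 1 / SQRT2], atol=1e-9)
    np.testing.assert_allclose(channel_weights(X).values, [SQRT2, SQRT2], atol=1e-9)


def test_uncorrelated_columns_closed_form(rng):
    """Exactly uncorrelated columns with variances (4, 1): |L| = identity,
    eigenvalues (4, 1), CWC = (4, 1)."""
    x = _two_column_window(rng)
    y = _two_column_window(rng)
    y = y - x * (x @ y) / (x @ x)          # orthogonalize exactly
    y = (y - y.mean()) / y.std(ddof=1)
    X = np.column_stack([2.0 * x, y])
    dec = pca_loadings(X)
    np.testing.assert_allclose(dec.eigenvalues, [4.0, 1.0], atol=1e-8)
    np.testing.assert_allclose(np.abs(dec.loadings), np.eye(2), atol=1e-8)
    np.testing.assert_allclose(channel_weights(X).values, [4.0, 1.0], atol=1e-8)


def test_covariance_reconstruction(rng):
    """L diag(s) L^T reproduces the sample covariance."""
    X = rng.standard_normal((256, 21))
    dec = pca_loadings(X)
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / (X.shape[0] - 1)
    recon = dec.loadings @ np.diag(dec.eigenvalues) @ dec.loadings.T
    assert np.abs(recon - S).max() < 1e-8
    # columns orthonormal
    np.testing.assert_allclose(dec.loadings.T @ dec.loadings, np.eye(21), atol=1e-8)
    assert np.all(np.diff(dec.eigenvalues) <= 1e-12)
    assert np.all(dec.eigenvalues >= 0.0)


def test_weighted_loadings_formula_and_homogeneity(rng):
    X = rng.standard_normal((64, 6))
    dec = pca_loadings(X)
    W = weighted_loadings(dec)
    np.testing.assert_allclose(W, np.abs(dec.loadings) * dec.eigenvalues, atol=0)
    # doubling one eigenvalue doubles exactly that column
    dec.eigenvalues[2] *= 2.0
    W2 = weighted_loadings(dec)
    np.testing.assert_allclose(W2[:, 2], 2 * W[:, 2])
    np.testing.assert_allclose(np.delete(W2, 2, axis=1), np.delete(W, 2, axis=1))


def test_eigen_path_matches_svd_oracle(rng):
    """Brute-force cross-check on small random windows."""
    for _ in range(50):
        X = rng.standard_normal((8, 4))
        np.testing.assert_allclose(channel_weights(X).values,
                                   channel_weights_svd(X), atol=1e-8)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000),
       st.floats(min_value=0.1, max_value=10.0))
def test_scale_equivariance(seed, a):
    """Scaling the window by a scales every CWC by a**2."""
    X = np.random.default_rng(seed).standard_normal((32, 5))
    base = channel_weights(X).values
    scaled = channel_weights(a * X).values
    np.testing.assert_allclose(scaled, a * a * base, rtol=1e-8)


def test_sign_invariance(rng):
    """Flipping any eigenvector's sign leaves the weights unchanged."""
    X = rng.standard_normal((64, 7))
    dec = pca_loadings(X)
    w = weighted_loadings(dec).sum(axis=1)
    dec.loadings[:, 3] *= -1.0
    np.testing.assert_allclose(weighted_loadings(dec).sum(axis=1), w)


def test_channel_permutation_equivariance(rng):
    X = rng.standard_normal((128, 9))
    perm = rng.permutation(9)
    np.testing.assert_allclose(channel_weights(X[:, perm]).values,
                               channel_weights(X).values[perm], atol=1e-9)


def test_ranking_invariant_to_covariance_normalization(rng):
    """1/N vs 1/(N-1) rescales all weights equally, preserving order."""
    X = rng.standard_normal((256, 21))
    w1 = channel_weights(X, ddof=1).values
    w0 = channel_weights(X, ddof=0).values
    np.testing.assert_array_equal(np.argsort(w1), np.argsort(w0))
    np.testing.assert_allclose(w0, w1 * 255 / 256, rtol=1e-10)


def test_constant_column_is_degenerate(rng):
    X = rng.standard_normal((16, 3))
    X[:, 1] = 2.5
    with pytest.raises(DegenerateWindowError):
        pca_loadings(X)


def test_series_shape_and_degenerate_rows(rng):
    sig = rng.standard_normal((4, 256 * 60 + 100))  # trailing fraction dropped
    series = cwc_series(sig, 256.0)
    assert series.matrix.shape == (60, 4)
    assert not np.isnan(series.matrix).any()
    sig[2, 256 * 10:256 * 11] = 0.0  # constant channel in window 10
    series = cwc_series(sig, 256.0)
    assert np.isnan(series.matrix[10]).all()
    assert not np.isnan(np.delete(series.matrix, 10, axis=0)).any()


def test_variance_boosted_channel_dominates(rng):
    """A channel with x10 variance during seconds 30-40 wins the row-wise
    argmax there in >= 9 of the 10 seconds."""
    sig = rng.standard_normal((21, 256 * 60))
    sig[8, 256 * 30:256 * 40] *= np.sqrt(10.0)
    series = cwc_series(sig, 256.0)
    hits = (series.matrix[30:40].argmax(axis=1) == 8).sum()
    assert hits >= 9


def test_rank_one_common_signal_gives_near_equal_weights(rng):
    """All channels carrying one common signal (plus tiny jitter): the
    single dominant component loads equally, so weights are near-equal."""
    common = rng.standard_normal(256 * 5)
    sig = np.tile(common, (6, 1)) + 1e-6 * rng.standard_normal((6, 256 * 5))
    series = cwc_series(sig, 256.0)
    spread = series.matrix.max(axis=1) / series.matrix.min(axis=1)
    assert np.all(spread < 1.001)
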