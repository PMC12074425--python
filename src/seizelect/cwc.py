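"""Channel weight coefficients (CWC) from the temporal PCA of 1-s windows.

For each 1-s window of a band-filtered multichannel signal, the sample
covariance across channels is eigen-decomposed. With loading matrix L
(columns = eigenvectors, orthonormal) and eigenvalues s_j (variance
explained by each principal component), the per-channel weight is

    CWC_i = sum_j |l_ij| * s_j

i.e. the absolute loadings weighted by explained variance and summed over
components. A channel that carries the dominant variance pattern of the
window receives a large weight; channels aligned only with noise
components receive small ones. Repeating the decomposition for every
non-overlapping 1-s window yields a (time x channels) series per band.

Properties used by the tests: scaling the window by ``a`` scales every CWC
by ``a**2`` (eigenvalues scale, absolute loadings do not); flipping an
eigenvector's sign changes nothing; channel permutations permute the CWC
vector identically; and the channel ranking does not depend on whether the
covariance uses 1/N or 1/(N-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegenerateWindowError(Exception):
    """A window has a constant channel; its covariance is rank-deficient in a
    way that makes the z-scored-channel premise invalid. Callers skip it."""


@dataclass
class LoadingDecomposition:
    """Eigen-decomposition of one window's channel covariance."""

    loadings: np.ndarray     # (C, C), columns orthonormal
    eigenvalues: np.ndarray  # (C,), descending, >= 0

    @property
    def n_channels(self) -> int:
        return self.loadings.shape[0]


@dataclass
class CWCVector:
    values: np.ndarray  # (C,), nonnegative
    start_s: float
    band: str = ""


@dataclass
class CWCSeries:
    """Per-second channel weights for one record and band.

    Row ``t`` is the CWC vector of the window starting at ``t`` seconds;
    degenerate windows leave a row of NaN.
    """

    matrix: np.ndarray  # (T, C)
    band: str
    record_id: str = ""

    @property
    def n_windows(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self, scheme=None):
        """CSV-friendly DataFrame: one row per second, one column per channel."""
        import pandas as pd

        if scheme is not None:
            cols = list(scheme.labels)
        else:
            cols = [f"ch{i + 1}" for i in range(self.matrix.shape[1])]
        df = pd.DataFrame(self.matrix, columns=cols)
        df.insert(0, "time_s", np.arange(self.matrix.shape[0], dtype=float))
        return df


def pca_loadings(X: np.ndarray, ddof: int = 1) -> LoadingDecomposition:
    """Eigen-decompose the sample covariance of a (N samples x C channels) window.

    Columns are mean-centered per window before the covariance (local means
    of a globally z-scored record are not exactly zero). Eigenvalues come
    out sorted descending and clipped at zero against floating-point
    negatives; the 1/(N-1) unbiased normalization is the default.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError(f"window must be (N>=2, C), got {X.shape}")
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.any(np.all(Xc == 0.0, axis=0)):
        raise DegenerateWindowError("window contains a constant channel")
    S = (Xc.T @ Xc) / (X.shape[0] - ddof)
    eigvals, eigvecs = np.linalg.eigh(S)        # ascending
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    return LoadingDecomposition(loadings=eigvecs[:, order], eigenvalues=eigvals)


def weighted_loadings(dec: LoadingDecomposition) -> np.ndarray:
    """Absolute loadings scaled column-wise by their eigenvalues.

    Element (i, j) = |l_ij| * s_j; nonnegative by construction.
    """
    return np.abs(dec.loadings) * dec.eigenvalues[np.newaxis, :]


def channel_weights(X: np.ndarray, ddof: int = 1, band: str = "",
                    start_s: float = 0.0) -> CWCVector:
    """CWC vector of one window: row sums of the weighted loading matrix."""
    dec = pca_loadings(X, ddof=ddof)
    return CWCVector(values=weighted_loadings(dec).sum(axis=1), start_s=start_s, band=band)


def channel_weights_svd(X: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Independent route to the same weights via the SVD of the centered data.

    With X_c = U diag(sv) V^T, the covariance eigenvectors are the columns
    of V and the eigenvalues are sv**2/(N-ddof). Kept separate from the
    eigen path as a cross-check oracle.
    """
    X = np.asarray(X, dtype=np.float64)
    Xc = X - X.mean(axis=0, keepdims=True)
    _, sv, Vt = np.linalg.svd(Xc, full_matrices=True)
    eig = np.zeros(X.shape[1])
    eig[: sv.size] = sv**2 / (X.shape[0] - ddof)
    return (np.abs(Vt.T) * eig[np.newaxis, :]).sum(axis=1)


def cwc_series(band_signal: np.ndarray, fs: float, band: str = "",
               record_id: str = "") -> CWCSeries:
    """Per-second CWC series over non-overlapping 1-s windows.

    ``band_signal`` is a (channels, T) band-filtered matrix. Windows start
    at 0, 1, 2, ... seconds; a trailing fraction of a second is dropped and
    a degenerate window yields a NaN row.
    """
    sig = np.asarray(band_signal, dtype=np.float64)
    n_per_win = int(round(fs))
    n_windows = sig.shape[1] // n_per_win
    C = sig.shape[0]
    out = np.full((n_windows, C), np.nan)
    for t in range(n_windows):
        X = sig[:, t * n_per_win:(t + 1) * n_per_win].T  # (N, C)
        try:
            out[t] = channel_weights(X).values
        except DegenerateWindowError:
            pass  # NaN row marks the skipped window
    return CWCSeries(matrix=out, band=band, record_id=record_id)
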