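"""Common Spatial Patterns for two-class variance discrimination.

Filters are generalized eigenvectors of the class covariance pair
(Sigma_A, Sigma_A + Sigma_B): the leading filters maximize the share of
variance explained by class A, the trailing ones by class B.  Per-window
spatial covariances are normalized by their trace before averaging so that
window-to-window amplitude differences do not dominate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg


class CSPWarning(UserWarning):
    pass


@dataclass
class BandCSP:
    """2m x channels spatial filter matrix for one frequency band."""

    filters: np.ndarray      # rows: m largest-eigenvalue then m smallest
    eigenvalues: np.ndarray  # matching, descending within each half

    @property
    def n_filters(self) -> int:
        return self.filters.shape[0]


def spatial_covariance(window: np.ndarray) -> np.ndarray:
    """Trace-normalized spatial covariance of a channels x samples window."""
    c = window @ window.T
    tr = np.trace(c)
    if tr <= 0:
        return np.eye(window.shape[0]) / window.shape[0]
    return c / tr


def class_covariance(windows: list[np.ndarray] | np.ndarray) -> np.ndarray:
    covs = [spatial_covariance(np.asarray(w, float)) for w in windows]
    return np.mean(covs, axis=0)


def fit_csp(
    windows_a: list[np.ndarray],
    windows_b: list[np.ndarray],
    m: int = 3,
    ridge: float = 1e-6,
) -> BandCSP:
    """Fit CSP filters from two sets of band-filtered windows.

    Returns the ``m`` largest- and ``m`` smallest-eigenvalue generalized
    eigenvectors of (Sigma_A, Sigma_A + Sigma_B).  A singular composite
    covariance triggers a ridge fallback with a warning.
    """
    if len(windows_a) < 2 or len(windows_b) < 2:
        raise ValueError("need at least 2 windows per class")
    n_ch = np.asarray(windows_a[0]).shape[0]
    if any(np.asarray(w).shape[0] != n_ch for w in windows_a + windows_b):
        raise ValueError("channel counts must match across windows")
    if 2 * m > n_ch:
        raise ValueError("2m cannot exceed the channel count")

    cov_a = class_covariance(windows_a)
    cov_b = class_covariance(windows_b)
    composite = cov_a + cov_b
    # rank check before the generalized solve
    if np.linalg.matrix_rank(composite) < n_ch:
        warnings.warn(
            "singular composite covariance; applying ridge regularization",
            CSPWarning,
        )
        composite = composite + ridge * np.trace(composite) / n_ch * np.eye(n_ch)

    evals, evecs = linalg.eigh(cov_a, composite)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    idx = np.concatenate([np.arange(m), np.arange(n_ch - m, n_ch)])
    return BandCSP(filters=evecs[:, idx].T.copy(), eigenvalues=evals[idx].copy())


def apply_csp(window: np.ndarray, band_csp: BandCSP) -> np.ndarray:
    """Project a channels x samples window onto the CSP filters."""
    return band_csp.filters @ np.asarray(window, float)
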