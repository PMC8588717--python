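"""Characteristic-band screening and PCA reduction to model input variables.

Band screening ranks wavelengths by the absolute Pearson correlation of
their (derivative) reflectance with TICS and keeps a fixed number of top
bands above an |r| cutoff.  PCA on the standardised selected features then
yields a small set of orthogonal scores used as regression inputs.

Three feature-set variants are built from one dataset:

* ``FD``         -- screened first-derivative bands -> PCA scores
* ``WPT-FD``     -- screened derivative bands of the WPT-denoised spectra -> PCA
* ``WPT-FD-HA``  -- the 12 harmonic parameters of the screened WPT-FD band
                    curve of each sample -> PCA
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .harmonics import harmonic_decompose, select_harmonic_parameters
from .preprocess import (
    WPTConfig,
    first_derivative_matrix,
    five_point_weighted_average,
    wpt_denoise,
)
from .spectra_io import SpectralDataset

__all__ = [
    "BandScreenResult",
    "PCAResult",
    "screen_bands",
    "pca_reduce",
    "build_feature_sets",
    "pearson_columns",
    "VARIANTS",
]

VARIANTS = ("FD", "WPT-FD", "WPT-FD-HA")


@dataclass
class BandScreenResult:
    """Outcome of correlation screening.

    ``band_indices`` are column positions into the screened matrix, sorted
    ascending (i.e. by wavelength); ``correlations`` the Pearson r of each
    selected band with the target; ``relaxed`` is set when fewer bands than
    requested exceeded the |r| cutoff and the ranking fell back to the top
    ``count`` by |r| regardless of the cutoff.
    """

    band_indices: np.ndarray
    correlations: np.ndarray
    threshold: float
    relaxed: bool = False


@dataclass
class PCAResult:
    """Scores and spectrum of a correlation-matrix PCA.

    ``eigenvalues`` are the variances of the score columns (eigenvalues of
    the correlation matrix of the inputs); contributions are percentages of
    total variance.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    variance_contribution: np.ndarray
    cumulative_contribution: np.ndarray
    components: np.ndarray = field(default=None)  # type: ignore[assignment]
    dropped_columns: np.ndarray = field(default=None)  # type: ignore[assignment]


def pearson_columns(features: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Pearson r of each column of ``features`` with ``target``.

    Zero-variance columns get r = 0 (flagged by the caller where needed).
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc ** 2, axis=0))
    sy = np.sqrt(np.sum(yc ** 2))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / denom
    r[denom == 0] = 0.0
    return r


def screen_bands(
    features: np.ndarray,
    tics: np.ndarray,
    threshold: float = 0.55,
    count: int = 150,
) -> BandScreenResult:
    """Select the characteristic bands most correlated with the target.

    Bands with |r| > ``threshold`` are ranked by |r| descending and the top
    ``count`` kept, then re-sorted by wavelength.  If fewer than ``count``
    bands pass the cutoff the selection falls back to the global top
    ``count`` by |r| and the result is flagged ``relaxed``.
    """
    features = np.asarray(features, dtype=float)
    tics = np.asarray(tics, dtype=float)
    if features.shape[0] < 3:
        raise ValueError("need at least 3 samples for correlation screening")
    if features.shape[1] < count:
        raise ValueError(f"only {features.shape[1]} bands available, {count} requested")
    r = pearson_columns(features, tics)
    absr = np.abs(r)
    passing = np.flatnonzero(absr > threshold)
    relaxed = passing.size < count
    # stable |r|-descending ranking; ties broken by band position
    order = np.argsort(-absr, kind="stable")
    if relaxed:
        chosen = order[:count]
    else:
        chosen = order[np.isin(order, passing)][:count]
    chosen = np.sort(chosen)
    return BandScreenResult(
        band_indices=chosen,
        correlations=r[chosen],
        threshold=threshold,
        relaxed=relaxed,
    )


def pca_reduce(
    features: np.ndarray,
    n_components: int = 5,
    min_cumulative: float = 90.0,
) -> PCAResult:
    """Correlation-matrix PCA returning exactly ``n_components`` scores.

    Columns are centred and scaled to unit (sample) variance before the
    eigendecomposition, so features with mixed units -- amplitudes and
    radian phases, say -- contribute on an equal footing.  Constant columns
    are dropped with a warning.  Component signs follow the convention that
    the largest-magnitude loading of each component is positive.  A warning
    is issued when the cumulative variance contribution of the retained
    components falls short of ``min_cumulative`` percent.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D feature matrix")
    n, p = x.shape
    if n <= n_components:
        raise ValueError(f"need more than {n_components} samples, got {n}")
    std = x.std(axis=0, ddof=1)
    dropped = np.flatnonzero(std == 0)
    if dropped.size:
        warnings.warn(f"dropping {dropped.size} constant column(s) before PCA", stacklevel=2)
        keep = np.flatnonzero(std > 0)
        x = x[:, keep]
        std = std[keep]
        p = x.shape[1]
    if p < n_components:
        raise ValueError(f"only {p} usable columns for {n_components} components")
    z = (x - x.mean(axis=0)) / std
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(z)
    components = pca.components_
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(components[np.arange(n_components), np.argmax(np.abs(components), axis=1)])
    flip[flip == 0] = 1.0
    scores = scores * flip
    components = components * flip[:, None]
    eigenvalues = pca.explained_variance_
    contribution = 100.0 * eigenvalues / p  # total variance of standardised data is p
    cumulative = np.cumsum(contribution)
    if cumulative[-1] < min_cumulative:
        warnings.warn(
            f"cumulative variance contribution {cumulative[-1]:.1f}% "
            f"below the {min_cumulative:.0f}% guideline",
            stacklevel=2,
        )
    return PCAResult(
        scores=scores,
        eigenvalues=eigenvalues,
        variance_contribution=contribution,
        cumulative_contribution=cumulative,
        components=components,
        dropped_columns=dropped,
    )


def _preprocessed_matrices(dataset: SpectralDataset, wpt_config: WPTConfig):
    """Smoothed FD matrix and WPT-denoised FD matrix for all samples."""
    smoothed = five_point_weighted_average(dataset.spectra)
    fd = first_derivative_matrix(dataset.wavelengths, smoothed)
    denoised = np.vstack([wpt_denoise(row, wpt_config) for row in smoothed])
    wpt_fd = first_derivative_matrix(dataset.wavelengths, denoised)
    return fd, wpt_fd


def build_feature_sets(
    dataset: SpectralDataset,
    wpt_config: WPTConfig | None = None,
    threshold: float = 0.55,
    count: int = 150,
    n_components: int = 5,
    harmonic_order: int = 150,
    min_cumulative: float = 90.0,
) -> dict:
    """Build the three PCA feature matrices (FD, WPT-FD, WPT-FD-HA).

    The chain per variant: five-point smoothing, optional WPT denoising,
    first derivative, correlation screening of ``count`` bands, then either
    PCA of those bands directly (FD, WPT-FD) or PCA of the 12 harmonic
    parameters of each sample's screened-band curve (WPT-FD-HA).

    Returns a dict with per-variant ``scores`` (n_samples x n_components),
    plus the screening and PCA result objects for reporting.
    """
    if wpt_config is None:
        wpt_config = WPTConfig()
    fd, wpt_fd = _preprocessed_matrices(dataset, wpt_config)
    tics = dataset.tics

    fd_screen = screen_bands(fd, tics, threshold, count)
    wpt_screen = screen_bands(wpt_fd, tics, threshold, count)

    fd_sel = fd[:, fd_screen.band_indices]
    wpt_sel = wpt_fd[:, wpt_screen.band_indices]

    ha_params = np.vstack([
        select_harmonic_parameters(harmonic_decompose(row, harmonic_order))
        for row in wpt_sel
    ])

    fd_pca = pca_reduce(fd_sel, n_components, min_cumulative)
    wpt_pca = pca_reduce(wpt_sel, n_components, min_cumulative)
    ha_pca = pca_reduce(ha_params, n_components, min_cumulative)

    return {
        "FD": {"scores": fd_pca.scores, "screen": fd_screen, "pca": fd_pca},
        "WPT-FD": {"scores": wpt_pca.scores, "screen": wpt_screen, "pca": wpt_pca},
        "WPT-FD-HA": {
            "scores": ha_pca.scores,
            "screen": wpt_screen,
            "pca": ha_pca,
            "harmonic_parameters": ha_params,
        },
    }
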