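"""Spectral noise suppression: weighted smoothing, first derivative, and
wavelet-packet best-basis denoising.

The processing chain mirrors the standard soil-spectroscopy workflow: a
five-point weighted moving average removes random single-band errors, the
first derivative (FD) removes linear baseline/background, and an optional
wavelet-packet transform (WPT) denoising step between the two suppresses
broadband noise before differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .spectra_io import Spectrum

__all__ = [
    "WPTConfig",
    "five_point_weighted_average",
    "first_derivative",
    "first_derivative_matrix",
    "soft_threshold",
    "wpt_denoise",
]

# Five-point window: weights 1/4, 1/2, 1, 1/2, 1/4 (sum 2.5), so the smoothed
# centre value is a true weighted mean.
_FIVE_POINT_WEIGHTS = np.array([0.25, 0.5, 1.0, 0.5, 0.25]) / 2.5


def five_point_weighted_average(values: np.ndarray) -> np.ndarray:
    """Five-point weighted moving average along the last axis.

    Interior points become ``(v[i-2]/4 + v[i-1]/2 + v[i] + v[i+1]/2 + v[i+2]/4)/2.5``;
    the first two and last two points are copied unchanged because the window
    is undefined there.

    Accepts a vector or a (n_samples, n_bands) matrix.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[-1] < 5:
        raise ValueError("need at least 5 points for the five-point window")
    out = values.copy()
    kernel = _FIVE_POINT_WEIGHTS
    if values.ndim == 1:
        out[2:-2] = np.convolve(values, kernel[::-1], mode="valid")
    else:
        smoothed = np.apply_along_axis(
            lambda row: np.convolve(row, kernel[::-1], mode="valid"), -1, values
        )
        out[..., 2:-2] = smoothed
    return out


def first_derivative(spectrum: Spectrum) -> Spectrum:
    """Central-difference first derivative of a reflectance spectrum.

    ``R'(l_i) = [R(l_{i+1}) - R(l_{i-1})] / (l_{i+1} - l_{i-1})`` at interior
    points, one-sided differences at the two endpoints.  Units are
    reflectance per nm.  Differentiation removes additive baseline offsets
    and attenuates linear background trends, which is why derivative spectra
    correlate with soil constituents far better than raw reflectance.
    """
    wl = spectrum.wavelengths
    if wl.size < 3:
        raise ValueError("need at least 3 bands for a central difference")
    deriv = first_derivative_matrix(wl, spectrum.reflectance)
    return Spectrum(wl, deriv)


def first_derivative_matrix(wavelengths: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Vectorised central difference along the last axis (rows = samples)."""
    wl = np.asarray(wavelengths, dtype=float)
    v = np.asarray(values, dtype=float)
    if wl.size < 3:
        raise ValueError("need at least 3 bands for a central difference")
    out = np.empty_like(v)
    out[..., 1:-1] = (v[..., 2:] - v[..., :-2]) / (wl[2:] - wl[:-2])
    out[..., 0] = (v[..., 1] - v[..., 0]) / (wl[1] - wl[0])
    out[..., -1] = (v[..., -1] - v[..., -2]) / (wl[-1] - wl[-2])
    return out


def soft_threshold(coefficient, threshold):
    """Soft shrinkage ``sign(x) * max(|x| - t, 0)``, continuous at +/-t."""
    if np.any(np.asarray(threshold) < 0):
        raise ValueError("threshold must be non-negative")
    x = np.asarray(coefficient, dtype=float)
    out = np.sign(x) * np.maximum(np.abs(x) - threshold, 0.0)
    return out if out.ndim else float(out)


@dataclass
class WPTConfig:
    """Wavelet-packet denoising settings.

    Parameters
    ----------
    wavelet : str
        Wavelet family; default ``db10`` (Daubechies, 10 vanishing moments),
        a common choice for smooth reflectance curves.
    max_level : int
        Depth of the full packet tree.  3 levels on a 2151-band spectrum
        keeps every subband above ~250 coefficients.
    cost : {"shannon", "log-energy"}
        Additive information cost minimised by the best-basis search.
    threshold : "universal" or float
        ``universal`` uses sigma * sqrt(2 ln L) with the noise scale sigma
        estimated from the finest-scale detail coefficients
        (median(|d1|)/0.6745); a float fixes the threshold directly.
    mode : str
        Signal extension mode of the filter bank (symmetric padding keeps
        edge artefacts small on reflectance curves).
    """

    wavelet: str = "db10"
    max_level: int = 3
    cost: str = "shannon"
    threshold: str | float = "universal"
    mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.max_level < 1:
            raise ValueError("max_level must be >= 1")
        if not isinstance(self.threshold, str) and self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        if self.cost not in ("shannon", "log-energy"):
            raise ValueError("cost must be 'shannon' or 'log-energy'")


def _node_cost(coeffs: np.ndarray, total_energy: float, kind: str) -> float:
    """Additive information cost of one packet node.

    Shannon cost uses p_i = c_i^2 / E with E the total signal energy, so that
    summing over any disjoint node cover is comparable across covers.
    """
    c2 = np.square(coeffs)
    if kind == "shannon":
        if total_energy <= 0:
            return 0.0
        p = c2 / total_energy
        nz = p[p > 0]
        return float(-np.sum(nz * np.log(nz)))
    # log-energy
    nz = c2[c2 > 0]
    return float(np.sum(np.log(nz))) if nz.size else 0.0


def _best_basis(wp: "pywt.WaveletPacket", max_level: int, kind: str) -> list[str]:
    """Coifman-Wickerhauser bottom-up best-basis search over the full tree."""
    total_energy = float(np.sum(np.square(wp.data)))
    best_cost: dict[str, float] = {}
    best_leaves: dict[str, list[str]] = {}
    for level in range(max_level, -1, -1):
        if level == 0:
            paths = [""]
        else:
            paths = ["".join(p) for p in _paths_at(level)]
        for path in paths:
            coeffs = np.asarray(wp[path].data if path else wp.data)
            own = _node_cost(coeffs, total_energy, kind)
            if level == max_level:
                best_cost[path] = own
                best_leaves[path] = [path]
            else:
                child_cost = best_cost[path + "a"] + best_cost[path + "d"]
                if own <= child_cost:
                    best_cost[path] = own
                    best_leaves[path] = [path]
                else:
                    best_cost[path] = child_cost
                    best_leaves[path] = best_leaves[path + "a"] + best_leaves[path + "d"]
    return best_leaves[""]


def _paths_at(level: int):
    import itertools

    return itertools.product("ad", repeat=level)


def wpt_denoise(values: np.ndarray, config: WPTConfig | None = None) -> np.ndarray:
    """Denoise a signal by soft-thresholding its best wavelet-packet basis.

    The procedure: (1) full packet decomposition to ``config.max_level``;
    (2) best-basis selection by additive-cost minimisation; (3) soft
    thresholding of every best-basis node except the pure low-frequency
    (approximation) node, which carries the curve shape; (4) inverse
    transform from the thresholded basis.  Output length equals input length.
    """
    if config is None:
        config = WPTConfig()
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("wpt_denoise expects a 1-D signal; map over rows for matrices")
    n = values.size
    admissible = pywt.dwt_max_level(n, pywt.Wavelet(config.wavelet).dec_len)
    if config.max_level > admissible:
        raise ValueError(
            f"max_level={config.max_level} too deep for length {n}; "
            f"maximum admissible level is {admissible}"
        )
    wp = pywt.WaveletPacket(values, config.wavelet, mode=config.mode, maxlevel=config.max_level)
    wp.get_level(config.max_level)  # force full decomposition
    basis = _best_basis(wp, config.max_level, config.cost)

    if isinstance(config.threshold, str):
        d1 = np.asarray(wp["d"].data)
        sigma = float(np.median(np.abs(d1))) / 0.6745
        thr = sigma * np.sqrt(2.0 * np.log(n))
    else:
        thr = float(config.threshold)

    if basis == [""]:
        return values.copy()

    node_data = {}
    for path in basis:
        coeffs = np.asarray(wp[path].data)
        if set(path) == {"a"}:  # lowest-frequency node: keep intact
            node_data[path] = coeffs
        else:
            node_data[path] = soft_threshold(coeffs, thr)

    # Bottom-up inverse transform.  The best basis mixes levels, so each
    # idwt output is trimmed to the known coefficient length of its parent
    # node (symmetric extension makes the raw output slightly longer).
    for level in range(max(len(p) for p in node_data), 0, -1):
        for path in [p for p in list(node_data) if len(p) == level]:
            if path not in node_data:  # sibling already merged
                continue
            parent = path[:-1]
            ca = node_data.pop(parent + "a")
            cd = node_data.pop(parent + "d")
            rec = pywt.idwt(ca, cd, config.wavelet, mode=config.mode)
            target = n if parent == "" else len(wp[parent].data)
            node_data[parent] = rec[:target]
    return node_data[""][:n]
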