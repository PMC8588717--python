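"""Harmonic (discrete Fourier-series) decomposition of spectral curves.

A preprocessed spectral curve of N bands, v_1..v_N, is treated as one period
of a discrete signal and expanded as

    V(k) = A0/2 + sum_h [ A_h cos(2*pi*h*k/N) + B_h sin(2*pi*h*k/N) ]
         = A0/2 + sum_h C_h sin(2*pi*h*k/N + phi_h),            k = 1..N

with

    A0/2  = (1/N) sum_k v_k                 (harmonic remainder, mean energy)
    A_h   = (2/N) sum_k v_k cos(2*pi*h*k/N) (cosine amplitude)
    B_h   = (2/N) sum_k v_k sin(2*pi*h*k/N) (sine amplitude)
    C_h   = sqrt(A_h^2 + B_h^2)             (component amplitude)
    phi_h = atan2(A_h, B_h)                 (phase, radians)

Low-order harmonics carry the broad energy structure of the curve; high
orders are dominated by noise, which is what makes a small set of low-order
parameters an effective, denoised feature vector.  Indexing is 1-based
(k = 1..N) inside the sums; phases would differ under 0-based indexing.

Note the aliasing relation on a length-N series: A_{N-h} = A_h and
B_{N-h} = -B_h, so orders above N/2 duplicate (up to sign) the information
below N/2.  Decomposing to order N is therefore harmless but redundant; only
the low orders are informative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HarmonicDecomposition",
    "harmonic_decompose",
    "harmonic_reconstruct",
    "select_harmonic_parameters",
    "component_target_correlation",
    "decompositions_to_table",
    "PARAMETER_NAMES",
]

#: Amplitudes below this are treated as zero when assigning a phase.
_PHASE_EPS = 1e-12

#: The 12 model parameters, in their fixed order.
PARAMETER_NAMES = (
    "A0_2",
    "A_1", "A_2", "A_3",
    "B_1", "B_2", "B_3",
    "C_1", "C_2", "C_3",
    "phi_1", "phi_2",
)


@dataclass
class HarmonicDecomposition:
    """Harmonic components of one curve: remainder, amplitudes and phases."""

    n_bands: int
    order: int
    remainder: float          # A0/2, the series mean
    cos_amp: np.ndarray       # A_h, h = 1..order
    sin_amp: np.ndarray       # B_h
    amplitude: np.ndarray     # C_h = sqrt(A_h^2 + B_h^2)
    phase: np.ndarray         # phi_h in (-pi, pi]

    def __post_init__(self) -> None:
        for name in ("cos_amp", "sin_amp", "amplitude", "phase"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.cos_amp) == len(self.sin_amp) == len(self.amplitude)
                == len(self.phase) == self.order):
            raise ValueError("component vectors must all have length `order`")


def harmonic_decompose(values: np.ndarray, order: int) -> HarmonicDecomposition:
    """Decompose a length-N curve into harmonics of orders 1..order."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-D series")
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 points")
    if order < 1:
        raise ValueError("order must be >= 1")
    k = np.arange(1, n + 1)
    h = np.arange(1, order + 1)
    angles = 2.0 * np.pi * np.outer(h, k) / n          # (order, N)
    cos_amp = (2.0 / n) * (np.cos(angles) @ v)
    sin_amp = (2.0 / n) * (np.sin(angles) @ v)
    amplitude = np.hypot(cos_amp, sin_amp)
    phase = np.arctan2(cos_amp, sin_amp)
    phase = np.where(amplitude < _PHASE_EPS, 0.0, phase)
    return HarmonicDecomposition(
        n_bands=n,
        order=order,
        remainder=float(np.mean(v)),
        cos_amp=cos_amp,
        sin_amp=sin_amp,
        amplitude=amplitude,
        phase=phase,
    )


def harmonic_reconstruct(dec: HarmonicDecomposition, order: int | None = None) -> np.ndarray:
    """Partial Fourier-series reconstruction using harmonics 1..order.

    With ``order`` equal to the full admissible order ((N-1)/2 for odd N)
    the reconstruction reproduces the original series exactly.
    """
    if order is None:
        order = dec.order
    if order > dec.order:
        raise ValueError(f"requested order {order} exceeds decomposition order {dec.order}")
    n = dec.n_bands
    k = np.arange(1, n + 1)
    out = np.full(n, dec.remainder)
    for idx in range(order):
        h = idx + 1
        angle = 2.0 * np.pi * h * k / n
        out = out + dec.cos_amp[idx] * np.cos(angle) + dec.sin_amp[idx] * np.sin(angle)
    return out


def select_harmonic_parameters(dec: HarmonicDecomposition) -> np.ndarray:
    """The fixed 12-parameter feature vector
    [A0/2, A1, A2, A3, B1, B2, B3, C1, C2, C3, phi1, phi2].

    The low-order remainder/amplitude/phase terms summarise the broad energy
    structure of the curve; they are the model inputs downstream.
    """
    if dec.order < 3:
        raise ValueError("decomposition order must be >= 3 for the 12-parameter set")
    return np.array([
        dec.remainder,
        dec.cos_amp[0], dec.cos_amp[1], dec.cos_amp[2],
        dec.sin_amp[0], dec.sin_amp[1], dec.sin_amp[2],
        dec.amplitude[0], dec.amplitude[1], dec.amplitude[2],
        dec.phase[0], dec.phase[1],
    ])


def decompositions_to_table(decs: list[HarmonicDecomposition]) -> pd.DataFrame:
    """One row per sample: A0_2, A_1.., B_1.., C_1.., phi_1.. columns."""
    if not decs:
        raise ValueError("no decompositions given")
    order = decs[0].order
    if any(d.order != order for d in decs):
        raise ValueError("all decompositions must share the same order")
    data = {"A0_2": [d.remainder for d in decs]}
    for prefix, attr in (("A", "cos_amp"), ("B", "sin_amp"), ("C", "amplitude"), ("phi", "phase")):
        for idx in range(order):
            data[f"{prefix}_{idx + 1}"] = [getattr(d, attr)[idx] for d in decs]
    return pd.DataFrame(data)


def component_target_correlation(
    decs: list[HarmonicDecomposition], tics: np.ndarray
) -> pd.DataFrame:
    """Pearson correlation of every harmonic component with the target.

    Returns a frame with columns ``component``, ``r`` and ``zero_variance``;
    a component that is constant across samples gets r = 0 with the flag set
    rather than NaN.
    """
    tics = np.asarray(tics, dtype=float)
    if len(decs) < 3 or tics.size != len(decs):
        raise ValueError("need >= 3 samples and matching target length")
    table = decompositions_to_table(decs)
    y = tics - tics.mean()
    sy = np.sqrt(np.sum(y ** 2))
    rows = []
    for col in table.columns:
        x = table[col].to_numpy()
        x = x - x.mean()
        sx = np.sqrt(np.sum(x ** 2))
        if sx == 0 or sy == 0:
            rows.append((col, 0.0, True))
        else:
            rows.append((col, float(np.sum(x * y) / (sx * sy)), False))
    return pd.DataFrame(rows, columns=["component", "r", "zero_variance"])
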