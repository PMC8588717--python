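"""Reading, writing and basic manipulation of soil reflectance spectra.

Spectra are vis-NIR reflectance curves (nominally 350-2500 nm, unitless
reflectance in [0, 1] with a small allowance above 1 for whiteboard-normalised
measurements).  Two on-disk layouts are supported, both plain delimited text:

* ``wide``  -- one row per sample, header ``sample_id, tics, soil_type, 350, 351, ...``
  where the numeric columns are wavelengths in nm (an optional ``nm`` suffix is
  tolerated, e.g. ``350nm``).
* ``long``  -- ``sample_id, wavelength, reflectance`` triples, with the
  per-sample targets (``sample_id, tics, soil_type``) in a companion table.

TICS (total iron content in soil) is the regression target, in g/kg.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectralDataset",
    "read_dataset",
    "write_dataset",
    "average_replicates",
    "resample_uniform",
]

#: Reflectance ceiling: BaSO4-whiteboard normalisation can push values a
#: little above 1 on bright targets.
REFLECTANCE_MAX = 1.5


@dataclass
class Spectrum:
    """A single reflectance spectrum on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths : ndarray
        Wavelengths in nm, strictly increasing.
    reflectance : ndarray
        Reflectance values (or a derived quantity such as a spectral
        derivative), same length as ``wavelengths``, all finite.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.ndim != 1 or self.reflectance.ndim != 1:
            raise ValueError("wavelengths and reflectance must be 1-D")
        if self.wavelengths.size != self.reflectance.size:
            raise ValueError(
                f"length mismatch: {self.wavelengths.size} wavelengths vs "
                f"{self.reflectance.size} reflectance values"
            )
        if self.wavelengths.size and np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains non-finite values")

    def __len__(self) -> int:
        return self.wavelengths.size


@dataclass
class SpectralDataset:
    """A collection of spectra on a shared grid with per-sample TICS targets.

    ``spectra`` is an ``(n_samples, n_bands)`` reflectance matrix; ``tics``
    holds the measured total iron content in g/kg (strictly positive);
    ``soil_type`` a categorical label per sample (e.g. ``loessial``/``sandy``).
    """

    sample_ids: list[str]
    wavelengths: np.ndarray
    spectra: np.ndarray
    tics: np.ndarray
    soil_type: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.tics = np.asarray(self.tics, dtype=float)
        if self.soil_type is None:
            self.soil_type = np.array(["unknown"] * len(self.sample_ids))
        else:
            self.soil_type = np.asarray(self.soil_type, dtype=object)
        n = len(self.sample_ids)
        if self.spectra.shape[0] != n or self.tics.size != n or self.soil_type.size != n:
            raise ValueError(
                "sample_ids, spectra rows, tics and soil_type must agree in length"
            )
        if self.spectra.shape[1] != self.wavelengths.size:
            raise ValueError("spectra columns must match the wavelength grid")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra contain non-finite values")
        if np.any(self.tics <= 0):
            raise ValueError("tics must be strictly positive (g/kg)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size

    def subset(self, index: np.ndarray) -> "SpectralDataset":
        """Row subset (boolean mask or integer index array)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SpectralDataset(
            sample_ids=[self.sample_ids[i] for i in index],
            wavelengths=self.wavelengths,
            spectra=self.spectra[index],
            tics=self.tics[index],
            soil_type=self.soil_type[index],
        )

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.wavelengths, self.spectra[i])


_META_COLUMNS = ("sample_id", "tics", "soil_type")


def _sep_for(path: str | os.PathLike) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def _parse_wavelength(name: str) -> float | None:
    """Parse a wavelength column name; tolerate a trailing ``nm``."""
    text = str(name).strip()
    if text.lower().endswith("nm"):
        text = text[:-2].strip()
    try:
        return float(text)
    except ValueError:
        return None


def read_dataset(
    path: str | os.PathLike,
    layout: str = "wide",
    targets: str | os.PathLike | None = None,
) -> SpectralDataset:
    """Read a spectral dataset from delimited text.

    Parameters
    ----------
    path : path
        The spectra table.  CSV/TSV is autodetected from the extension.
    layout : {"wide", "long"}
        See the module docstring for the two layouts.
    targets : path, optional
        For the long layout, the companion targets table
        (``sample_id, tics, soil_type``).  Ignored for wide.

    Raises
    ------
    ValueError
        On a missing ``tics`` column ("targets missing"), duplicate or
        non-monotone wavelengths, or missing reflectance cells.
    """
    sep = _sep_for(path)
    if layout == "wide":
        frame = pd.read_csv(path, sep=sep)
        if "tics" not in frame.columns:
            raise ValueError(f"targets missing: no 'tics' column in {path}")
        if "sample_id" not in frame.columns:
            raise ValueError(f"no 'sample_id' column in {path}")
        wl_cols = []
        for col in frame.columns:
            if col in _META_COLUMNS:
                continue
            wl = _parse_wavelength(col)
            if wl is None:
                raise ValueError(f"unrecognised column {col!r}: not metadata, not a wavelength")
            wl_cols.append((wl, col))
        if not wl_cols:
            raise ValueError("no wavelength columns found")
        wavelengths = np.array([w for w, _ in wl_cols])
        if np.unique(wavelengths).size != wavelengths.size:
            dup = wl_cols[int(np.flatnonzero(np.diff(np.sort(wavelengths)) == 0)[0])][1]
            raise ValueError(f"duplicate wavelength column near {dup!r}")
        order = np.argsort(wavelengths)  # tolerate shuffled exports
        wavelengths = wavelengths[order]
        cols = [wl_cols[i][1] for i in order]
        spectra = frame[cols].to_numpy(dtype=float)
        if np.isnan(spectra).any():
            raise ValueError("missing reflectance cells are not allowed")
        soil = frame["soil_type"].to_numpy() if "soil_type" in frame.columns else None
        return SpectralDataset(
            sample_ids=list(frame["sample_id"].astype(str)),
            wavelengths=wavelengths,
            spectra=spectra,
            tics=frame["tics"].to_numpy(dtype=float),
            soil_type=soil,
        )
    if layout == "long":
        if targets is None:
            raise ValueError("targets missing: long layout requires a targets table")
        frame = pd.read_csv(path, sep=sep)
        required = {"sample_id", "wavelength", "reflectance"}
        if not required.issubset(frame.columns):
            raise ValueError(f"long layout needs columns {sorted(required)}")
        tgt = pd.read_csv(targets, sep=_sep_for(targets))
        if "tics" not in tgt.columns:
            raise ValueError(f"targets missing: no 'tics' column in {targets}")
        wide = frame.pivot(index="sample_id", columns="wavelength", values="reflectance")
        if wide.isna().any().any():
            raise ValueError("missing reflectance cells are not allowed")
        tgt = tgt.set_index(tgt["sample_id"].astype(str))
        ids = [str(s) for s in wide.index]
        missing = [s for s in ids if s not in tgt.index]
        if missing:
            raise ValueError(f"targets missing for samples: {missing[:5]}")
        tgt = tgt.loc[ids]
        soil = tgt["soil_type"].to_numpy() if "soil_type" in tgt.columns else None
        return SpectralDataset(
            sample_ids=ids,
            wavelengths=wide.columns.to_numpy(dtype=float),
            spectra=wide.to_numpy(dtype=float),
            tics=tgt["tics"].to_numpy(dtype=float),
            soil_type=soil,
        )
    raise ValueError(f"unknown layout {layout!r}; expected 'wide' or 'long'")


def write_dataset(dataset: SpectralDataset, path: str | os.PathLike) -> None:
    """Write a dataset in the wide layout (CSV/TSV by extension)."""
    frame = pd.DataFrame(dataset.spectra, columns=[repr(float(w)) for w in dataset.wavelengths])
    frame.insert(0, "soil_type", dataset.soil_type)
    frame.insert(0, "tics", dataset.tics)
    frame.insert(0, "sample_id", dataset.sample_ids)
    frame.to_csv(path, sep=_sep_for(path), index=False)


def average_replicates(spectra: list[Spectrum]) -> Spectrum:
    """Element-wise mean of replicate scans on identical wavelength grids.

    Replicate field scans of the same soil sample are averaged into a single
    spectrum to suppress instrument instability.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    grid = spectra[0].wavelengths
    for s in spectra[1:]:
        if s.wavelengths.size != grid.size or not np.allclose(s.wavelengths, grid, rtol=0, atol=0):
            raise ValueError("replicate spectra must share an identical wavelength grid")
    mean = np.mean([s.reflectance for s in spectra], axis=0)
    return Spectrum(grid, mean)


def resample_uniform(spectrum: Spectrum, start: float, stop: float, step: float) -> Spectrum:
    """Linearly interpolate a spectrum onto the uniform grid start:step:stop.

    The grid is inclusive of ``stop`` when ``(stop - start)`` is an integer
    multiple of ``step``.  Extrapolation outside the source range is refused.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    src = spectrum.wavelengths
    if start < src[0] or stop > src[-1]:
        raise ValueError(
            f"extrapolation requested: [{start}, {stop}] outside source range "
            f"[{src[0]}, {src[-1]}]"
        )
    n = int(round((stop - start) / step))
    grid = start + step * np.arange(n + 1)
    grid = grid[grid <= stop + 1e-9]
    values = np.interp(grid, src, spectrum.reflectance)
    return Spectrum(grid, values)
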