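"""Shared spectral data model.

The whole pipeline moves one currency around: a :class:`SpectrumSet`, i.e. a
wavenumber grid plus a stack of spectra with per-row provenance (which sample,
which imaging area, which histopathological class) and a ``mode`` flag that
records where in the transmission -> absorbance -> derivative chain the data
currently sit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Allowed data modes, in the only order transitions may occur.
MODES = ("transmission", "absorbance", "derivative")

#: Histopathological class codes: H = hyperkeratosis, D = dysplasia, C = OSCC.
CLASS_CODES = ("H", "D", "C")

#: Per-row roles: raw imaging pixels vs. per-area representative spectra.
ROLES = ("pixel", "representative")

#: Metadata columns every SpectrumSet row must carry.
REQUIRED_META = ("sample_id", "area_id", "class_label", "role")


@dataclass(frozen=True)
class WavenumberGrid:
    """A strictly descending wavenumber axis in cm^-1.

    Descending order (high -> low wavenumber) is the spectroscopy plotting
    convention and the canonical in-memory order here; ascending input is the
    caller's responsibility to flip (the file readers do this and say so).
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("wavenumber grid must be a 1-D array of >= 2 points")
        if not np.all(np.diff(values) < 0):
            raise ValueError("wavenumber grid must be strictly descending")
        values.flags.writeable = False
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return np.array_equal(self.values, other.values)

    @property
    def spacing(self) -> float:
        """Median absolute grid step in cm^-1."""
        return float(np.median(np.abs(np.diff(self.values))))

    def nearest_index(self, wavenumber: float) -> int:
        """Index of the grid point closest to ``wavenumber``."""
        return int(np.argmin(np.abs(self.values - wavenumber)))

    def region_mask(self, high: float, low: float) -> np.ndarray:
        """Boolean mask of points inside [low, high] (inclusive)."""
        if high < low:
            high, low = low, high
        return (self.values >= low) & (self.values <= high)


def make_grid(high: float = 1800.0, low: float = 950.0, step: float = 2.0) -> WavenumberGrid:
    """Build a descending grid from ``high`` down to ``low`` inclusive."""
    n = int(round((high - low) / step)) + 1
    return WavenumberGrid(np.linspace(high, low, n))


@dataclass
class SpectrumSet:
    """A stack of spectra on a common grid with per-row provenance.

    Parameters
    ----------
    grid:
        Shared wavenumber axis (descending).
    intensities:
        ``(n_spectra, n_wavenumbers)`` array. Units depend on ``mode``.
    meta:
        One row per spectrum; must contain ``sample_id``, ``area_id``,
        ``class_label`` and ``role`` columns. Extra columns (e.g. synthetic
        ground-truth tissue labels) ride along untouched.
    mode:
        One of ``transmission | absorbance | derivative``.
    """

    grid: WavenumberGrid
    intensities: np.ndarray
    meta: pd.DataFrame
    mode: str = "absorbance"

    def __post_init__(self) -> None:
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.intensities.shape[1] != len(self.grid):
            raise ValueError(
                f"intensities have {self.intensities.shape[1]} columns but the "
                f"grid has {len(self.grid)} wavenumbers"
            )
        if len(self.meta) != self.intensities.shape[0]:
            raise ValueError("meta must have one row per spectrum")
        missing = [c for c in REQUIRED_META if c not in self.meta.columns]
        if missing:
            raise ValueError(f"meta is missing required columns: {missing}")
        if self.meta["sample_id"].isna().any():
            raise ValueError("every row must carry a sample_id")
        self.meta = self.meta.reset_index(drop=True)

    # -- basic introspection -------------------------------------------------

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    def __len__(self) -> int:
        return self.n_spectra

    @property
    def classes(self) -> np.ndarray:
        return self.meta["class_label"].to_numpy()

    @property
    def sample_ids(self) -> np.ndarray:
        return self.meta["sample_id"].to_numpy()

    # -- derived sets ----------------------------------------------------------

    def with_intensities(self, intensities: np.ndarray, mode: str | None = None) -> "SpectrumSet":
        """Same provenance, new data (and possibly new mode)."""
        return SpectrumSet(
            grid=self.grid,
            intensities=np.asarray(intensities, dtype=float),
            meta=self.meta.copy(),
            mode=self.mode if mode is None else mode,
        )

    def select_rows(self, index: np.ndarray) -> "SpectrumSet":
        """Subset rows by boolean mask or integer index array."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SpectrumSet(
            grid=self.grid,
            intensities=self.intensities[index],
            meta=self.meta.iloc[index].reset_index(drop=True),
            mode=self.mode,
        )

    def select_columns(self, mask: np.ndarray) -> "SpectrumSet":
        """Subset wavenumbers by boolean mask, preserving grid order."""
        mask = np.asarray(mask, dtype=bool)
        return SpectrumSet(
            grid=WavenumberGrid(self.grid.values[mask]),
            intensities=self.intensities[:, mask],
            meta=self.meta.copy(),
            mode=self.mode,
        )

    def groupby(self, column: str) -> Iterable[tuple[str, "SpectrumSet"]]:
        """Yield ``(key, subset)`` pairs grouped by a metadata column, sorted."""
        for key in sorted(self.meta[column].unique()):
            yield key, self.select_rows((self.meta[column] == key).to_numpy())

    def copy(self) -> "SpectrumSet":
        return self.with_intensities(self.intensities.copy())

    def band_mean(self, center: float, half_width: float = 4.0) -> np.ndarray:
        """Per-row mean intensity in a window ``center +/- half_width`` cm^-1."""
        mask = self.grid.region_mask(center + half_width, center - half_width)
        if not mask.any():
            raise ValueError(f"no grid points within {half_width} of {center}")
        return self.intensities[:, mask].mean(axis=1)


def concat(sets: Sequence[SpectrumSet]) -> SpectrumSet:
    """Stack multiple SpectrumSets sharing one grid and mode."""
    if not sets:
        raise ValueError("nothing to concatenate")
    first = sets[0]
    for s in sets[1:]:
        if s.grid != first.grid:
            raise ValueError("cannot concatenate sets on different grids")
        if s.mode != first.mode:
            raise ValueError("cannot concatenate sets in different modes")
    return SpectrumSet(
        grid=first.grid,
        intensities=np.vstack([s.intensities for s in sets]),
        meta=pd.concat([s.meta for s in sets], ignore_index=True),
        mode=first.mode,
    )


def make_meta(
    sample_id: str | Sequence[str],
    area_id: str | Sequence[str],
    class_label: str | Sequence[str],
    role: str = "pixel",
    n: int | None = None,
    **extra: Sequence,
) -> pd.DataFrame:
    """Convenience constructor for a provenance frame."""
    if n is None:
        lengths = [len(v) for v in (sample_id, area_id, class_label) if not isinstance(v, str)]
        n = lengths[0] if lengths else 1
    data = {
        "sample_id": [sample_id] * n if isinstance(sample_id, str) else list(sample_id),
        "area_id": [area_id] * n if isinstance(area_id, str) else list(area_id),
        "class_label": [class_label] * n if isinstance(class_label, str) else list(class_label),
        "role": [role] * n if isinstance(role, str) else list(role),
    }
    for key, value in extra.items():
        data[key] = [value] * n if isinstance(value, str) else list(value)
    return pd.DataFrame(data)
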