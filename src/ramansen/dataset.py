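"""Core containers: a single spectrum and a labelled collection on a shared grid."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

CLASS_LABELS = ("HOL", "MinSOL-H", "ModSOL-H", "MinSOL", "ModSOL", "SOL")

#: Visual senescence stage index used for trend fitting (subclasses share the
#: stage of the tissue they were sampled from being visually green).
STAGE_INDEX = {
    "HOL": 0,
    "MinSOL-H": 0,
    "ModSOL-H": 0,
    "MinSOL": 1,
    "ModSOL": 2,
    "SOL": 3,
}

DEFAULT_RANGE = (690.0, 1655.0)


class DatasetError(ValueError):
    """Raised on malformed spectral data or incompatible grids."""


@dataclass
class Spectrum:
    """One Raman measurement: wavenumber grid (cm^-1) + intensities (a.u.).

    Metadata carries ``sample_id``, ``map_id`` and ``class_label`` when known,
    plus processing flags (e.g. ``baseline_converged``).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise DatasetError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.size != self.intensities.size:
            raise DatasetError(
                f"length mismatch: {self.wavenumbers.size} wavenumbers vs "
                f"{self.intensities.size} intensities"
            )
        if self.wavenumbers.size < 2:
            raise DatasetError("a spectrum needs at least 2 points")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise DatasetError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise DatasetError("intensities must be finite")

    def __len__(self) -> int:
        return self.wavenumbers.size

    def copy(self, intensities: np.ndarray | None = None, **meta) -> "Spectrum":
        md = dict(self.metadata)
        md.update(meta)
        return Spectrum(
            self.wavenumbers.copy(),
            self.intensities.copy() if intensities is None else np.asarray(intensities, float),
            md,
        )

    def nearest_index(self, wavenumber: float) -> int:
        """Index of the grid point nearest ``wavenumber``; ties break low."""
        w = self.wavenumbers
        if wavenumber < w[0] or wavenumber > w[-1]:
            raise DatasetError(
                f"wavenumber {wavenumber} outside spectral span [{w[0]}, {w[-1]}]"
            )
        d = np.abs(w - wavenumber)
        # argmin returns the first (lowest-wavenumber) minimiser, which is the
        # documented tie-break.
        return int(np.argmin(d))

    def intensity_at(self, wavenumber: float) -> float:
        return float(self.intensities[self.nearest_index(wavenumber)])


class SpectralDataset:
    """Labelled spectra sharing one wavenumber grid.

    Stored as an ``(n_spectra, n_points)`` intensity matrix plus a metadata
    table with ``sample_id``, ``map_id`` and ``class_label`` columns.
    """

    def __init__(self, grid: np.ndarray, intensities: np.ndarray, meta: pd.DataFrame):
        self.grid = np.asarray(grid, dtype=float)
        self.intensities = np.asarray(intensities, dtype=float)
        if self.intensities.ndim != 2 or self.intensities.shape[1] != self.grid.size:
            raise DatasetError("intensity matrix does not match grid length")
        if len(meta) != self.intensities.shape[0]:
            raise DatasetError("metadata rows do not match number of spectra")
        for col in ("sample_id", "map_id", "class_label"):
            if col not in meta.columns:
                raise DatasetError(f"metadata missing column {col!r}")
        if not np.all(np.diff(self.grid) > 0):
            raise DatasetError("grid must be strictly increasing")
        self.meta = meta.reset_index(drop=True)

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return self.intensities.shape[0]

    def __iter__(self) -> Iterator[Spectrum]:
        for i in range(len(self)):
            yield self.spectrum(i)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralDataset):
            return NotImplemented
        return (
            np.array_equal(self.grid, other.grid)
            and np.array_equal(self.intensities, other.intensities)
            and self.meta.reset_index(drop=True).equals(other.meta.reset_index(drop=True))
        )

    def spectrum(self, i: int) -> Spectrum:
        row = self.meta.iloc[i]
        return Spectrum(
            self.grid,
            self.intensities[i],
            {
                "sample_id": row["sample_id"],
                "map_id": row["map_id"],
                "class_label": row["class_label"],
            },
        )

    @property
    def labels(self) -> np.ndarray:
        return self.meta["class_label"].to_numpy()

    @property
    def class_labels(self) -> list[str]:
        """Distinct class labels in canonical order where possible."""
        present = set(self.meta["class_label"])
        ordered = [c for c in CLASS_LABELS if c in present]
        extras = sorted(present - set(ordered))
        return ordered + extras

    def subset(self, classes: Iterable[str]) -> "SpectralDataset":
        keep = set(classes)
        mask = self.meta["class_label"].isin(keep).to_numpy()
        if not mask.any():
            raise DatasetError(f"no spectra left after subsetting to {sorted(keep)}")
        return SpectralDataset(self.grid, self.intensities[mask], self.meta[mask])

    def map_transform(self, fn) -> "SpectralDataset":
        """Apply a Spectrum -> Spectrum function to every spectrum.

        The transform must preserve the grid (truncation returns a new common
        grid, which is fine as long as it is identical across spectra).
        """
        out = [fn(s) for s in self]
        return from_spectra(out)

    def to_long_frame(self) -> pd.DataFrame:
        n, p = self.intensities.shape
        return pd.DataFrame(
            {
                "sample_id": np.repeat(self.meta["sample_id"].to_numpy(), p),
                "map_id": np.repeat(self.meta["map_id"].to_numpy(), p),
                "class": np.repeat(self.meta["class_label"].to_numpy(), p),
                "wavenumber_cm1": np.tile(self.grid, n),
                "intensity_au": self.intensities.ravel(),
            }
        )


def from_spectra(spectra: Sequence[Spectrum], resample: bool = False) -> SpectralDataset:
    """Assemble a dataset from individual spectra.

    All spectra must share a grid unless ``resample`` is set, in which case
    each spectrum is linearly interpolated onto the union of all grids.
    """
    if not spectra:
        raise DatasetError("empty spectrum list")
    grids = [s.wavenumbers for s in spectra]
    same = all(np.array_equal(grids[0], g) for g in grids[1:])
    if not same:
        if not resample:
            raise DatasetError(
                "spectra are on different grids; pass resample=True to interpolate "
                "onto the union grid"
            )
        union = np.unique(np.concatenate(grids))
        mat = np.vstack([np.interp(union, s.wavenumbers, s.intensities) for s in spectra])
        grid = union
    else:
        grid = grids[0]
        mat = np.vstack([s.intensities for s in spectra])
    meta = pd.DataFrame(
        {
            "sample_id": [s.metadata.get("sample_id", f"S{i}") for i, s in enumerate(spectra)],
            "map_id": [s.metadata.get("map_id", "") for s in spectra],
            "class_label": [s.metadata.get("class_label", "") for s in spectra],
        }
    )
    return SpectralDataset(grid, mat, meta)
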