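"""Preprocessing chain: IO, cosmic-ray removal, iterative polynomial baseline
subtraction, range truncation and reference-peak normalisation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_widths

from .dataset import DatasetError, SpectralDataset, Spectrum, from_spectra


class ParseError(ValueError):
    """Malformed spectral input file."""


class NormalizationError(ValueError):
    """Zero or negative reference intensity."""


@dataclass
class BaselineConfig:
    polynomial_order: int = 11
    noise_tolerance: float = 1.5  # multiplies the residual SD (one-sided)
    max_iterations: int = 100

    def __post_init__(self) -> None:
        if self.polynomial_order < 0:
            raise ValueError("polynomial_order must be >= 0")
        if self.noise_tolerance <= 0:
            raise ValueError("noise_tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

LONG_COLUMNS = ["sample_id", "map_id", "class", "wavenumber_cm1", "intensity_au"]


def read_dataset(path: str | Path, format: str = "long-tsv", resample: bool = False) -> SpectralDataset:
    """Read a dataset from a long-format TSV file or a directory of
    two-column per-spectrum CSV files.

    Raises :class:`ParseError` naming the offending record for malformed rows
    or non-monotone grids; spectra on different grids require ``resample``.
    """
    path = Path(path)
    if format == "long-tsv":
        return _read_long_tsv(path, resample)
    if format == "csv-dir":
        return _read_csv_dir(path, resample)
    raise ValueError(f"unknown format {format!r} (expected 'long-tsv' or 'csv-dir')")


def write_dataset(dataset: SpectralDataset, path: str | Path, format: str = "long-tsv") -> Path:
    path = Path(path)
    if format == "long-tsv":
        path.parent.mkdir(parents=True, exist_ok=True)
        # %.17g guarantees bit-exact float64 round-tripping
        dataset.to_long_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")
        return path
    if format == "csv-dir":
        path.mkdir(parents=True, exist_ok=True)
        for s in dataset:
            out = path / f"{s.metadata['sample_id']}.csv"
            header = (
                f"# sample_id={s.metadata['sample_id']} map_id={s.metadata['map_id']} "
                f"class={s.metadata['class_label']}\n"
            )
            with open(out, "w") as fh:
                fh.write(header)
                fh.write("wavenumber_cm1,intensity_au\n")
                for w, i in zip(s.wavenumbers, s.intensities):
                    fh.write(f"{float(w)!r},{float(i)!r}\n")
        return path
    raise ValueError(f"unknown format {format!r}")


def _read_long_tsv(path: Path, resample: bool) -> SpectralDataset:
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in ("wavenumber_cm1", "intensity_au"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 1-based
            raise ParseError(
                f"{path}: non-numeric value {df[col][bad].iloc[0]!r} in column "
                f"{col!r} at line {line}"
            )
        if converted.isna().any():
            line = int(np.flatnonzero(converted.isna().to_numpy())[0]) + 2
            raise ParseError(f"{path}: missing value in column {col!r} at line {line}")
        # astype parses round-trip exactly (pd.to_numeric's parser does not)
        df[col] = df[col].astype(float)
    spectra = []
    for sid, g in df.groupby("sample_id", sort=False):
        w = g["wavenumber_cm1"].to_numpy(float)
        if not np.all(np.diff(w) > 0):
            raise ParseError(f"{path}: non-monotone wavenumber grid for sample {sid!r}")
        spectra.append(
            Spectrum(
                w,
                g["intensity_au"].to_numpy(float),
                {
                    "sample_id": sid,
                    "map_id": g["map_id"].iloc[0],
                    "class_label": g["class"].iloc[0],
                },
            )
        )
    try:
        return from_spectra(spectra, resample=resample)
    except DatasetError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _read_csv_dir(path: Path, resample: bool) -> SpectralDataset:
    if not path.is_dir():
        raise FileNotFoundError(path)
    spectra = []
    for csv in sorted(path.glob("*.csv")):
        meta = {"sample_id": csv.stem, "map_id": "", "class_label": ""}
        with open(csv) as fh:
            first = fh.readline()
        skip = 0
        if first.startswith("#"):
            skip = 1
            for token in first[1:].split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    key = {"class": "class_label"}.get(k, k)
                    meta[key] = v
        df = pd.read_csv(csv, skiprows=skip, float_precision="round_trip")
        try:
            w = df.iloc[:, 0].astype(float).to_numpy()
            y = df.iloc[:, 1].astype(float).to_numpy()
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{csv}: non-numeric data ({exc})") from exc
        if not np.all(np.diff(w) > 0):
            raise ParseError(f"{csv}: non-monotone wavenumber grid")
        spectra.append(Spectrum(w, y, meta))
    if not spectra:
        raise ParseError(f"{path}: no CSV spectra found")
    try:
        return from_spectra(spectra, resample=resample)
    except DatasetError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Cosmic-ray removal
# ---------------------------------------------------------------------------


def remove_cosmic_rays(s: Spectrum, max_feature_width: int = 2) -> Spectrum:
    """Replace narrow high-prominence excursions by linear interpolation.

    An excursion is removed when its full width above half its prominence
    spans at most ``max_feature_width`` grid points and its prominence exceeds
    a robust noise floor; genuine Raman bands (FWHM >> grid step) survive
    untouched. Spike-free spectra are returned unchanged.
    """
    if max_feature_width < 1:
        raise ValueError("max_feature_width must be >= 1")
    y = s.intensities
    # Robust scale of point-to-point noise from second differences.
    d2 = np.diff(y, 2)
    noise = float(np.median(np.abs(d2)) / 0.6745 / np.sqrt(6)) if d2.size else 0.0
    min_prom = max(6.0 * noise, 1e-12)
    peaks, props = find_peaks(y, prominence=min_prom)
    if peaks.size == 0:
        return s.copy()
    widths = peak_widths(y, peaks, rel_height=0.5)[0]
    spikes = peaks[widths <= max_feature_width]
    if spikes.size == 0:
        return s.copy()
    out = y.copy()
    mask = np.zeros(y.size, dtype=bool)
    half = int(np.ceil(max_feature_width / 2))
    for p in spikes:
        mask[max(0, p - half) : min(y.size, p + half + 1)] = True
    good = ~mask
    out[mask] = np.interp(s.wavenumbers[mask], s.wavenumbers[good], y[good])
    return s.copy(intensities=out, cosmic_rays_removed=int(spikes.size))


# ---------------------------------------------------------------------------
# Baseline subtraction (iterative restrained polynomial, ModPoly-style)
# ---------------------------------------------------------------------------


def subtract_baseline(s: Spectrum, cfg: BaselineConfig | None = None) -> Spectrum:
    """Subtract an iteratively fitted polynomial background.

    Points lying more than ``noise_tolerance`` residual-SDs *above* the
    current polynomial are excluded from the next fit (Raman peaks are
    positive); iteration stops when the excluded set is stable or after
    ``max_iterations``. Non-convergence sets ``baseline_converged=False`` in
    the result metadata instead of raising.
    """
    cfg = cfg or BaselineConfig()
    if len(s) <= cfg.polynomial_order + 1:
        raise ValueError(
            f"need more than order+1={cfg.polynomial_order + 1} points, got {len(s)}"
        )
    x, y = s.wavenumbers, s.intensities
    include = np.ones(y.size, dtype=bool)
    converged = False
    poly = None
    for _ in range(cfg.max_iterations):
        poly = np.polynomial.Polynomial.fit(x[include], y[include], cfg.polynomial_order)
        fit = poly(x)
        resid = y - fit
        sd = float(np.std(resid[include]))
        scale = max(float(np.max(np.abs(y))), 1.0)
        if sd <= 1e-10 * scale:  # fit already explains the data to rounding
            converged = True
            break
        new_include = resid <= cfg.noise_tolerance * sd
        if np.array_equal(new_include, include):
            converged = True
            break
        if not new_include.any() or new_include.sum() <= cfg.polynomial_order + 1:
            converged = True  # cannot shrink further; keep current fit
            break
        include = new_include
    if not converged:
        warnings.warn("baseline fit did not converge", RuntimeWarning, stacklevel=2)
    return s.copy(intensities=y - poly(x), baseline_converged=converged)


# ---------------------------------------------------------------------------
# Truncation and normalisation
# ---------------------------------------------------------------------------


def truncate(s: Spectrum, lo: float = 690.0, hi: float = 1655.0) -> Spectrum:
    if lo >= hi:
        raise ValueError("need lo < hi")
    mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if mask.sum() < 2:
        raise DatasetError(f"no spectral points left in [{lo}, {hi}]")
    return Spectrum(s.wavenumbers[mask], s.intensities[mask], dict(s.metadata))


def normalize_at(s: Spectrum, ref_wavenumber: float = 1003.0) -> Spectrum:
    """Divide all intensities by the intensity at the grid point nearest the
    reference wavenumber (the 1003 cm^-1 carotenoid/phenylalanine band)."""
    ref = s.intensity_at(ref_wavenumber)
    if ref <= 0:
        raise NormalizationError(
            f"reference intensity at {ref_wavenumber} cm^-1 is {ref}; cannot normalise"
        )
    return s.copy(intensities=s.intensities / ref, normalized_at=ref_wavenumber)


def preprocess(
    s: Spectrum,
    cosmic_width: int = 2,
    baseline: BaselineConfig | None = None,
    lo: float = 690.0,
    hi: float = 1655.0,
    normalize: float | None = None,
) -> Spectrum:
    """Full chain: cosmic removal -> baseline subtraction -> truncation
    (-> optional normalisation)."""
    out = remove_cosmic_rays(s, cosmic_width)
    out = subtract_baseline(out, baseline)
    out = truncate(out, lo, hi)
    if normalize is not None:
        out = normalize_at(out, normalize)
    return out
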