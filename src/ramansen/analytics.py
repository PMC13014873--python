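"""Derived per-spectrum statistics: peak intensities and ratios, the
crystalline-cellulose index, Simpson's-rule region areas, trend fits and
small instrument utilities."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .dataset import DatasetError, SpectralDataset, Spectrum

#: Intensity-ratio pairs (a, b) reported throughout: chlorophyll-a behaviour,
#: carbohydrate-lignin, phenylalanine-carotenoid and chlorophyll-a/alpha-amyrin.
DEFAULT_RATIOS = ((700.0, 1147.0), (898.0, 1606.0), (1003.0, 1525.0), (1226.0, 1456.0))

#: Integration regions surrounding the 907, 1020, 1128 and 1272 cm^-1 bands.
DEFAULT_REGIONS = (
    ("860-970", 860.0, 970.0),
    ("980-1055", 980.0, 1055.0),
    ("1095-1170", 1095.0, 1170.0),
    ("1205-1335", 1205.0, 1335.0),
)


@dataclass(frozen=True)
class RegionSpec:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (690.0 <= self.lo < self.hi <= 1655.0):
            raise ValueError(f"region [{self.lo}, {self.hi}] must satisfy 690 <= lo < hi <= 1655")


@dataclass
class FitResult:
    model: str  # 'linear' | 'exponential'
    parameters: tuple[float, ...]
    r_squared: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.model == "linear":
            slope, intercept = self.parameters
            return slope * x + intercept
        a, b = self.parameters
        return a * np.exp(b * x)


# ---------------------------------------------------------------------------
# Peak readouts
# ---------------------------------------------------------------------------


def peak_intensity(s: Spectrum, wavenumber: float, window: float = 0.0) -> float:
    """Intensity at the nearest grid point, or the maximum within +/- window."""
    if window < 0:
        raise ValueError("window must be >= 0")
    if window == 0:
        return s.intensity_at(wavenumber)
    w = s.wavenumbers
    if wavenumber < w[0] or wavenumber > w[-1]:
        raise DatasetError(f"wavenumber {wavenumber} outside spectral span")
    mask = (w >= wavenumber - window) & (w <= wavenumber + window)
    return float(np.max(s.intensities[mask]))


def peak_ratio(s: Spectrum, a: float, b: float) -> float:
    """I(a) / I(b) using nearest-grid-point intensities."""
    denom = s.intensity_at(b)
    if denom == 0:
        raise ZeroDivisionError(f"zero intensity at denominator wavenumber {b} cm^-1")
    return s.intensity_at(a) / denom


def crystallinity(s: Spectrum) -> float:
    """Cellulose crystallinity index X_c = I(1481) / (I(1462) + I(1481)),
    the crystalline fraction of the CH2 scissoring doublet."""
    i62 = s.intensity_at(1462.0)
    i81 = s.intensity_at(1481.0)
    denom = i62 + i81
    if denom == 0:
        raise ZeroDivisionError("I(1462) + I(1481) is zero")
    return i81 / denom


# ---------------------------------------------------------------------------
# Region areas
# ---------------------------------------------------------------------------


def _composite_simpson(x: np.ndarray, y: np.ndarray) -> float:
    """Composite Simpson's rule; a trailing odd interval is handled by the
    trapezoid rule on that final interval."""
    n_int = x.size - 1
    total = 0.0
    end = n_int if n_int % 2 == 0 else n_int - 1
    for i in range(0, end, 2):
        h1 = x[i + 1] - x[i]
        h2 = x[i + 2] - x[i + 1]
        # Non-uniform Simpson (exact for quadratics on unequal panels).
        h = h1 + h2
        total += (h / 6.0) * (
            y[i] * (2.0 - h2 / h1) + y[i + 1] * h * h / (h1 * h2) + y[i + 2] * (2.0 - h1 / h2)
        )
    if end != n_int:
        total += 0.5 * (x[-1] - x[-2]) * (y[-1] + y[-2])
    return float(total)


def simpson_area(s: Spectrum, region: RegionSpec | None = None) -> float:
    """Simpson's-rule integral of the spectrum over a region (or full span)."""
    if region is None:
        x, y = s.wavenumbers, s.intensities
    else:
        mask = (s.wavenumbers >= region.lo) & (s.wavenumbers <= region.hi)
        if mask.sum() < 3:
            raise DatasetError(
                f"region {region.name} contains {int(mask.sum())} grid points; need >= 3"
            )
        x, y = s.wavenumbers[mask], s.intensities[mask]
    return _composite_simpson(x, y)


def relative_region_area(
    s: Spectrum, region: RegionSpec, full_lo: float = 690.0, full_hi: float = 1655.0
) -> float:
    """Region area divided by the full-range area."""
    total = simpson_area(s, RegionSpec("full", full_lo, full_hi))
    if total == 0:
        raise ZeroDivisionError("full-range area is zero")
    return simpson_area(s, region) / total


# ---------------------------------------------------------------------------
# Trend fitting
# ---------------------------------------------------------------------------


def fit_trend(x, y, model: str = "linear") -> FitResult:
    """OLS line or A*exp(b*x) nonlinear least squares (log-linear initialised);
    R^2 is computed on the original scale as 1 - SS_res/SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all values equal")
    if model == "linear":
        slope, intercept = np.polyfit(x, y, 1)
        pred = slope * x + intercept
        params = (float(slope), float(intercept))
    elif model == "exponential":
        if np.any(y <= 0):
            raise ValueError("exponential model requires y > 0")
        b0, loga0 = np.polyfit(x, np.log(y), 1)
        popt, _ = curve_fit(
            lambda t, a, b: a * np.exp(b * t), x, y, p0=(np.exp(loga0), b0), maxfev=10000
        )
        pred = popt[0] * np.exp(popt[1] * x)
        params = (float(popt[0]), float(popt[1]))
    else:
        raise ValueError(f"unknown model {model!r}")
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FitResult(model=model, parameters=params, r_squared=r2)


# ---------------------------------------------------------------------------
# RGB channel means
# ---------------------------------------------------------------------------


def rgb_channel_means(image: np.ndarray, mask: np.ndarray | None = None) -> tuple[float, float, float]:
    """Per-channel arithmetic mean over (optionally masked) pixels."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3 or img.size == 0:
        raise ValueError("image must be a non-empty (H, W, 3) array")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != img.shape[:2]:
            raise ValueError("mask shape must match image height x width")
        if not mask.any():
            raise ValueError("empty mask")
        img = img[mask]
        return tuple(float(v) for v in img.mean(axis=0))
    return tuple(float(v) for v in img.reshape(-1, 3).mean(axis=0))


# ---------------------------------------------------------------------------
# Instrument utilities
# ---------------------------------------------------------------------------


def spot_size(wavelength_nm: float, numerical_aperture: float) -> float:
    """Diffraction-limited spot diameter 1.22*lambda/NA in micrometres,
    reported to two decimals."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be > 0")
    if not (0 < numerical_aperture <= 1):
        raise ValueError("numerical aperture must be in (0, 1]")
    return round(1.22 * wavelength_nm / numerical_aperture / 1000.0, 2)


def total_integration_time(acquisition_s: float, accumulations: int) -> float:
    if acquisition_s <= 0 or accumulations <= 0:
        raise ValueError("acquisition time and accumulations must be positive")
    return acquisition_s * accumulations


# ---------------------------------------------------------------------------
# Tidy per-dataset tables
# ---------------------------------------------------------------------------


def region_table(dataset: SpectralDataset, regions=None, relative: bool = True) -> pd.DataFrame:
    regions = [RegionSpec(*r) for r in (regions or DEFAULT_REGIONS)]
    rows = []
    for s in dataset:
        rec = {"sample_id": s.metadata["sample_id"], "class": s.metadata["class_label"]}
        for r in regions:
            rec[r.name] = (
                relative_region_area(s, r) if relative else simpson_area(s, r)
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def ratio_table(dataset: SpectralDataset, ratios=DEFAULT_RATIOS) -> pd.DataFrame:
    rows = []
    for s in dataset:
        rec = {"sample_id": s.metadata["sample_id"], "class": s.metadata["class_label"]}
        for a, b in ratios:
            rec[f"{a:g}/{b:g}"] = peak_ratio(s, a, b)
        rows.append(rec)
    return pd.DataFrame(rows)


def crystallinity_table(dataset: SpectralDataset) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": s.metadata["sample_id"],
                "class": s.metadata["class_label"],
                "crystallinity": crystallinity(s),
            }
            for s in dataset
        ]
    )
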