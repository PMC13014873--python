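"""Seeded synthetic data: class-labelled Raman spectra, absorbances, RGB patches.

The six-class generator emulates the statistical structure the downstream
analyses assume: shared biomolecule peaks whose amplitudes follow the
qualitative senescence trends, a class-dependent global intensity scale
(residual chlorophyll-a fluorescence), a smooth additive baseline, Gaussian
noise and sparse single-point cosmic-ray spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import CLASS_LABELS, STAGE_INDEX, DatasetError, SpectralDataset

DEFAULT_GRID = (690.0, 1655.0, 1.0)
DEFAULT_FWHM = 12.0  # cm^-1, typical solid-state Raman band width


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def lorentzian(x: np.ndarray, center: float, amplitude: float, fwhm: float) -> np.ndarray:
    """Peak-amplitude Lorentzian: value ``amplitude`` at ``center``."""
    g = fwhm / 2.0
    return amplitude * g * g / ((x - center) ** 2 + g * g)


def lorentzian_area(amplitude: float, fwhm: float, center: float, lo: float, hi: float) -> float:
    """Closed-form integral of the peak-amplitude Lorentzian over [lo, hi]."""
    g = fwhm / 2.0
    return amplitude * g * (np.arctan((hi - center) / g) + np.arctan((center - lo) / g))


@dataclass
class ClassTemplate:
    """Per-class spectral recipe.

    ``peaks`` holds ``(center, base_amplitude, fwhm, multiplier)`` tuples; the
    effective noiseless signal is the sum of Lorentzians with amplitude
    ``base_amplitude * multiplier``, globally scaled by a draw from
    ``fluorescence_scale = (mean, sd)``. ``fluorescence_scale2`` enables a
    second mixture component (used for the bimodal SOL intensity mode).
    ``baseline_coeffs`` are polynomial coefficients in the normalised grid
    coordinate u in [0, 1], additive in a.u.
    """

    class_label: str
    peaks: list[tuple[float, float, float, float]]
    fluorescence_scale: tuple[float, float]
    baseline_coeffs: tuple[float, ...] = (40.0, -25.0, 15.0)
    noise_sd: float = 18.0
    spike_rate: float = 0.3
    fluorescence_scale2: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ConfigError(f"unknown class label {self.class_label!r}")
        for c, a, w, m in self.peaks:
            if not (690.0 <= c <= 1655.0):
                raise ConfigError(f"peak center {c} outside [690, 1655] cm^-1")
            if a < 0 or w < 0 or m < 0:
                raise ConfigError("peak amplitude, FWHM and multiplier must be >= 0")
        if self.noise_sd < 0 or self.spike_rate < 0:
            raise ConfigError("noise_sd and spike_rate must be >= 0")

    def clean_signal(self, grid: np.ndarray) -> np.ndarray:
        """Noiseless unit-scale peak sum (no baseline, no fluorescence scale)."""
        y = np.zeros_like(grid, dtype=float)
        for c, a, w, m in self.peaks:
            if a * m > 0:
                y += lorentzian(grid, c, a * m, w)
        return y

    def baseline(self, grid: np.ndarray) -> np.ndarray:
        u = (grid - grid[0]) / (grid[-1] - grid[0])
        return np.polynomial.polynomial.polyval(u, np.asarray(self.baseline_coeffs))

    def analytic_peak_area(self, lo: float, hi: float) -> float:
        """Sum of closed-form Lorentzian areas over [lo, hi] at unit scale."""
        return float(
            sum(lorentzian_area(a * m, w, c, lo, hi) for c, a, w, m in self.peaks if a * m > 0)
        )

    def multiplier_at(self, center: float) -> float:
        for c, _a, _w, m in self.peaks:
            if abs(c - center) < 1e-9:
                return m
        raise KeyError(f"no template peak at {center} cm^-1")


@dataclass
class SimulationConfig:
    n_per_class: int = 100
    acquisitions_per_map: int = 10
    grid: tuple[float, float, float] = DEFAULT_GRID
    seed: int = 0
    class_templates: list[ClassTemplate] = field(default_factory=list)

    def __post_init__(self) -> None:
        start, stop, step = self.grid
        if step <= 0 or stop <= start:
            raise ConfigError("invalid grid: need stop > start and step > 0")
        if self.n_per_class <= 0 or self.acquisitions_per_map <= 0:
            raise ConfigError("counts must be positive")
        if self.n_per_class % self.acquisitions_per_map != 0:
            raise ConfigError("n_per_class must be divisible by acquisitions_per_map")
        if not self.class_templates:
            self.class_templates = default_templates()

    def grid_array(self) -> np.ndarray:
        start, stop, step = self.grid
        n = int(round((stop - start) / step)) + 1
        return start + step * np.arange(n)


# ---------------------------------------------------------------------------
# Default templates
# ---------------------------------------------------------------------------

# center -> (base amplitude, FWHM, multipliers for
#            HOL, MinSOL-H, ModSOL-H, MinSOL, ModSOL, SOL)
# Trends: chlorophyll/carotenoid bands decay toward SOL; 898/907/1020/1128/1272
# grow toward SOL; 854 rises to ModSOL then falls; 917/1606 roughly stable.
_PEAK_TABLE: dict[float, tuple[float, float, tuple[float, ...]]] = {
    700.0: (0.30, DEFAULT_FWHM, (1.00, 1.00, 0.85, 0.80, 0.50, 0.30)),
    744.0: (0.35, DEFAULT_FWHM, (1.00, 0.95, 0.80, 0.75, 0.45, 0.15)),
    854.0: (0.25, DEFAULT_FWHM, (1.00, 1.00, 1.00, 1.20, 1.50, 0.70)),
    898.0: (0.30, DEFAULT_FWHM, (0.30, 0.35, 0.45, 0.80, 1.60, 2.60)),
    907.0: (0.30, DEFAULT_FWHM, (0.00, 0.00, 0.00, 0.30, 0.80, 2.80)),
    917.0: (0.35, DEFAULT_FWHM, (1.00, 1.00, 1.00, 1.00, 1.00, 1.00)),
    1003.0: (0.90, 10.0, (1.00, 1.00, 0.85, 0.80, 0.50, 0.55)),
    1020.0: (0.25, DEFAULT_FWHM, (0.30, 0.30, 0.35, 0.80, 1.60, 3.20)),
    1048.0: (0.30, DEFAULT_FWHM, (1.00, 1.00, 1.00, 1.10, 1.20, 1.40)),
    1128.0: (0.30, DEFAULT_FWHM, (0.30, 0.30, 0.35, 0.80, 1.70, 3.00)),
    1147.0: (0.45, DEFAULT_FWHM, (1.00, 1.00, 0.85, 0.70, 0.40, 0.25)),
    1157.0: (0.85, 10.0, (1.00, 1.00, 0.85, 0.75, 0.50, 0.30)),
    1218.0: (0.30, DEFAULT_FWHM, (1.00, 1.00, 1.00, 0.95, 0.80, 0.80)),
    1226.0: (0.35, DEFAULT_FWHM, (1.00, 1.00, 0.85, 0.80, 0.50, 0.60)),
    1272.0: (0.30, DEFAULT_FWHM, (0.10, 0.20, 0.35, 0.60, 1.60, 3.40)),
    1288.0: (0.35, DEFAULT_FWHM, (0.90, 0.90, 0.90, 1.00, 1.20, 1.80)),
    1309.0: (0.25, DEFAULT_FWHM, (0.80, 0.80, 0.80, 0.90, 1.10, 1.60)),
    1328.0: (0.50, DEFAULT_FWHM, (1.00, 1.00, 0.85, 0.80, 0.55, 0.50)),
    1343.0: (0.30, DEFAULT_FWHM, (0.90, 0.90, 0.90, 0.95, 1.00, 1.50)),
    1355.0: (0.30, DEFAULT_FWHM, (0.80, 0.80, 0.80, 0.90, 1.00, 1.50)),
    1451.0: (0.27, DEFAULT_FWHM, (0.90, 0.90, 0.90, 1.00, 1.10, 1.60)),
    1456.0: (0.35, DEFAULT_FWHM, (1.00, 1.00, 1.00, 1.00, 1.10, 1.50)),
    1462.0: (0.50, DEFAULT_FWHM, (1.00, 1.00, 1.00, 1.00, 1.00, 1.00)),
    # 1481 crystalline-cellulose amplitude is solved per class below.
    1490.0: (0.06, DEFAULT_FWHM, (1.00, 1.00, 1.00, 1.00, 1.00, 1.00)),
    1494.0: (0.25, DEFAULT_FWHM, (1.00, 0.95, 0.80, 0.80, 0.50, 0.25)),
    1495.0: (0.06, DEFAULT_FWHM, (1.00, 1.00, 1.00, 1.00, 1.00, 1.00)),
    1510.0: (0.06, DEFAULT_FWHM, (1.00, 1.00, 1.00, 1.00, 1.00, 0.00)),
    1525.0: (1.00, 10.0, (1.00, 1.05, 0.85, 0.80, 0.45, 0.25)),
    1606.0: (0.60, DEFAULT_FWHM, (1.00, 1.00, 1.00, 1.00, 1.05, 1.15)),
}

#: Noiseless crystallinity targets per class (monotone non-decreasing; the
#: SOL endpoint matches the printed fully-senesced value 0.594).
_XC_TARGETS = (0.20, 0.21, 0.22, 0.23, 0.27, 0.594)

#: Fluorescence scale (mean, sd) per class; the first three match the printed
#: per-class maximum-intensity summaries, the rest continue the chlorophyll
#: decline. SOL gets a two-component intensity mixture.
_FLUORESCENCE = {
    "HOL": (3375.18, 541.57),
    "MinSOL-H": (5317.59, 542.38),
    "ModSOL-H": (4239.02, 718.79),
    "MinSOL": (2800.0, 500.0),
    "ModSOL": (1800.0, 450.0),
    "SOL": (9942.69, 700.0),
}
_SOL_SECOND_MODE = (14493.02, 750.0)


def _solve_1481_amplitude(peaks: list[tuple[float, float, float, float]], target: float) -> float:
    """Amplitude of the 1481 cm^-1 band so the noiseless crystallinity
    I(1481)/(I(1462)+I(1481)) equals ``target`` at the 1462/1481 grid points.

    Linear in the unknown amplitude because every other band is fixed.
    """
    o62 = sum(lorentzian(np.array([1462.0]), c, a * m, w)[0] for c, a, w, m in peaks)
    o81 = sum(lorentzian(np.array([1481.0]), c, a * m, w)[0] for c, a, w, m in peaks)
    cross = lorentzian(np.array([1462.0]), 1481.0, 1.0, DEFAULT_FWHM)[0]
    denom = 1.0 - target * (1.0 + cross)
    amp = (target * (o81 + o62) - o81) / denom
    if amp <= 0:
        raise ConfigError(
            f"crystallinity target {target} unreachable with the fixed band set"
        )
    return amp


def default_templates(sol_bimodal: bool = True) -> list[ClassTemplate]:
    """Six class templates following the qualitative senescence trends.

    Each template is normalised so its noiseless peak-sum maximum on the
    default grid is 1.0; the fluorescence scale therefore sets the expected
    spectrum maximum directly.
    """
    start, stop, step = DEFAULT_GRID
    x = start + step * np.arange(int(round((stop - start) / step)) + 1)
    templates = []
    for ci, label in enumerate(CLASS_LABELS):
        peaks = [
            (c, base, w, mults[ci]) for c, (base, w, mults) in _PEAK_TABLE.items()
        ]
        a81 = _solve_1481_amplitude(peaks, _XC_TARGETS[ci])
        peaks.append((1481.0, a81, DEFAULT_FWHM, 1.0))
        tmpl = ClassTemplate(
            class_label=label,
            peaks=sorted(peaks),
            fluorescence_scale=_FLUORESCENCE[label],
            fluorescence_scale2=_SOL_SECOND_MODE if (label == "SOL" and sol_bimodal) else None,
        )
        peak_max = tmpl.clean_signal(x).max()
        tmpl.peaks = [(c, a / peak_max, w, m) for c, a, w, m in tmpl.peaks]
        templates.append(tmpl)
    return templates


# ---------------------------------------------------------------------------
# Spectrum simulation
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimulationConfig) -> SpectralDataset:
    """Generate ``n_per_class`` spectra per class on the common grid.

    spectrum = fluorescence_draw * peak_sum + baseline + N(0, noise_sd)
               + Poisson(spike_rate) cosmic-ray spikes.

    Deterministic for a fixed seed; map identifiers are assigned in blocks of
    ``acquisitions_per_map``.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid_array()
    rows: list[np.ndarray] = []
    meta_rows: list[dict] = []
    for tmpl in config.class_templates:
        signal = tmpl.clean_signal(grid)
        baseline = tmpl.baseline(grid)
        label = tmpl.class_label
        for i in range(config.n_per_class):
            scale = _draw_scale(rng, tmpl)
            y = scale * signal + baseline
            if tmpl.noise_sd > 0:
                y = y + rng.normal(0.0, tmpl.noise_sd, size=grid.size)
            y = _add_spikes(rng, y, tmpl.spike_rate)
            rows.append(y)
            map_idx = i // config.acquisitions_per_map + 1
            meta_rows.append(
                {
                    "sample_id": f"{label}-{i + 1}",
                    "map_id": f"{label}-map{map_idx}",
                    "class_label": label,
                }
            )
    return SpectralDataset(grid, np.vstack(rows), pd.DataFrame(meta_rows))


def _draw_scale(rng: np.random.Generator, tmpl: ClassTemplate) -> float:
    mean, sd = tmpl.fluorescence_scale
    if tmpl.fluorescence_scale2 is not None and rng.random() < 0.5:
        mean, sd = tmpl.fluorescence_scale2
    draw = rng.normal(mean, sd) if sd > 0 else mean
    return max(draw, 0.05 * mean)


def _add_spikes(rng: np.random.Generator, y: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return y
    n_spikes = rng.poisson(rate)
    if n_spikes == 0:
        return y
    y = y.copy()
    for _ in range(n_spikes):
        pos = rng.integers(0, y.size)
        lo, hi = max(0, pos - 5), min(y.size, pos + 6)
        local = max(float(np.max(np.abs(y[lo:hi]))), 1.0)
        y[pos] += rng.uniform(5.0, 20.0) * local
    return y


# ---------------------------------------------------------------------------
# Absorbance and RGB patches
# ---------------------------------------------------------------------------

#: Negative-exponential absorbance model A(stage) = A0 * exp(-k * stage) with
#: endpoints matching the printed HOL (1.67) and SOL (0.298) values.
_ABS_A0 = 1.67
_ABS_K = float(np.log(1.67 / 0.298) / 3.0)


def absorbance_curve(stage: np.ndarray | float) -> np.ndarray | float:
    return _ABS_A0 * np.exp(-_ABS_K * np.asarray(stage, dtype=float))


def simulate_absorbance(
    classes: list[str], seed: int = 0, noise_sd: float = 0.02
) -> list[tuple[str, float]]:
    """One A600 draw per requested class label (repeats allowed)."""
    rng = np.random.default_rng(seed)
    out = []
    for label in classes:
        if label not in STAGE_INDEX:
            raise ConfigError(f"unknown class label {label!r}")
        a = float(absorbance_curve(STAGE_INDEX[label]))
        if noise_sd > 0:
            a += rng.normal(0.0, noise_sd)
        out.append((label, a))
    return out


#: Class mean (R, G, B): green-dominant for HOL/MinSOL (and -H subclasses),
#: all channels raised for ModSOL (yellowing), red > green for SOL (browning).
_RGB_MEANS = {
    "HOL": (60.0, 125.0, 45.0),
    "MinSOL-H": (58.0, 122.0, 44.0),
    "ModSOL-H": (60.0, 120.0, 46.0),
    "MinSOL": (70.0, 125.0, 48.0),
    "ModSOL": (140.0, 150.0, 70.0),
    "SOL": (120.0, 85.0, 55.0),
}


def simulate_rgb_patch(
    class_label: str,
    size: tuple[int, int] = (32, 32),
    seed: int = 0,
    noise_sd: float = 8.0,
) -> np.ndarray:
    """Uint8 (H, W, 3) patch with per-pixel channels drawn around the class
    mean triple, clipped to [0, 255]."""
    if class_label not in _RGB_MEANS:
        raise ConfigError(f"unknown class label {class_label!r}")
    h, w = (size, size) if isinstance(size, int) else size
    if h < 1 or w < 1:
        raise ConfigError("patch size must be at least 1x1")
    rng = np.random.default_rng(seed)
    mean = np.array(_RGB_MEANS[class_label])
    img = np.broadcast_to(mean, (h, w, 3)).astype(float).copy()
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Serialisation helpers (long TSV / per-spectrum CSV live in prep.io)
# ---------------------------------------------------------------------------


def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "n_per_class": config.n_per_class,
        "acquisitions_per_map": config.acquisitions_per_map,
        "grid": list(config.grid),
        "seed": config.seed,
        "class_templates": [
            {
                "class_label": t.class_label,
                "peaks": [list(p) for p in t.peaks],
                "fluorescence_scale": list(t.fluorescence_scale),
                "fluorescence_scale2": (
                    list(t.fluorescence_scale2) if t.fluorescence_scale2 else None
                ),
                "baseline_coeffs": list(t.baseline_coeffs),
                "noise_sd": t.noise_sd,
                "spike_rate": t.spike_rate,
            }
            for t in config.class_templates
        ],
    }


def config_from_dict(d: dict) -> SimulationConfig:
    templates = [
        ClassTemplate(
            class_label=t["class_label"],
            peaks=[tuple(p) for p in t["peaks"]],
            fluorescence_scale=tuple(t["fluorescence_scale"]),
            fluorescence_scale2=(
                tuple(t["fluorescence_scale2"]) if t.get("fluorescence_scale2") else None
            ),
            baseline_coeffs=tuple(t["baseline_coeffs"]),
            noise_sd=t["noise_sd"],
            spike_rate=t["spike_rate"],
        )
        for t in d.get("class_templates", [])
    ]
    return SimulationConfig(
        n_per_class=d["n_per_class"],
        acquisitions_per_map=d["acquisitions_per_map"],
        grid=tuple(d["grid"]),
        seed=d["seed"],
        class_templates=templates,
    )
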