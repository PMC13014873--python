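"""Simulated chlorophyll-catabolite vibrational line lists: parsing, the
top-5/activity-30 filter, stage tallies, Lorentzian-broadened rendering,
spatially-unique band grouping and matching against per-class peak tables."""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError, field_validator

from .dataset import Spectrum

STAGES = ("early", "quasi-mid", "mid", "late")
DEFAULT_RANGE = (690.0, 1655.0)


class VibrationalLine(BaseModel):
    mode: int
    wavenumber_cm1: float = Field(gt=0)
    activity_A4_AMU: float = Field(ge=0)


class CataboliteLineList(BaseModel):
    """One simulated catabolite's vibrational lines plus stage annotation."""

    name: str
    stage: str
    lines: list[VibrationalLine]

    @field_validator("stage")
    @classmethod
    def _known_stage(cls, v: str) -> str:
        if v not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {v!r}")
        return v

    def sorted_lines(self) -> list[VibrationalLine]:
        return sorted(self.lines, key=lambda l: l.wavenumber_cm1)


class LineListError(ValueError):
    pass


def parse_linelist(path: str | Path) -> CataboliteLineList:
    """Load and validate a line-list JSON record; lines come back sorted by
    wavenumber. Schema errors carry the pydantic location path."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise LineListError(f"{path}: invalid JSON ({exc})") from exc
    try:
        ll = CataboliteLineList.model_validate(payload)
    except ValidationError as exc:
        raise LineListError(f"{path}: schema error: {exc}") from exc
    return CataboliteLineList(name=ll.name, stage=ll.stage, lines=ll.sorted_lines())


def write_linelist(ll: CataboliteLineList, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(ll.model_dump_json())
    return path


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_top_peaks(
    ll: CataboliteLineList,
    k: int = 5,
    min_activity: float = 30.0,
    wn_range: tuple[float, float] = DEFAULT_RANGE,
) -> pd.DataFrame:
    """Restrict to the wavenumber range, take the k highest-activity lines,
    then discount any with activity below ``min_activity``; rows are sorted by
    descending activity."""
    lo, hi = wn_range
    in_range = [l for l in ll.lines if lo <= l.wavenumber_cm1 <= hi]
    top = sorted(in_range, key=lambda l: l.activity_A4_AMU, reverse=True)[:k]
    kept = [l for l in top if l.activity_A4_AMU >= min_activity]
    return pd.DataFrame(
        [
            {
                "wavenumber_cm1": l.wavenumber_cm1,
                "catabolite": ll.name,
                "stage": ll.stage,
                "activity_A4_AMU": l.activity_A4_AMU,
                "mode": l.mode,
            }
            for l in kept
        ],
        columns=["wavenumber_cm1", "catabolite", "stage", "activity_A4_AMU", "mode"],
    )


def stage_counts(table: pd.DataFrame) -> dict[str, int]:
    """Tally of filtered peaks per catabolism stage plus the total."""
    if "stage" not in table.columns:
        raise ValueError("table has no 'stage' column")
    if len(table) and table["stage"].isna().any():
        raise ValueError("rows with missing stage annotation")
    counts = {s: 0 for s in STAGES}
    for s, n in table["stage"].value_counts().items():
        if s not in counts:
            raise ValueError(f"unknown stage {s!r}")
        counts[s] = int(n)
    counts["total"] = int(len(table))
    return counts


def load_filtered_peak_table() -> pd.DataFrame:
    """Packaged transcription of the filtered simulated-catabolite peak table
    (wavenumber, catabolite, stage superscript, refined stage, annotation,
    spatially-unique flag)."""
    with resources.files("ramansen.data").joinpath("table3_filtered_peaks.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_assignment_table() -> pd.DataFrame:
    """Packaged experimental band-assignment table."""
    with resources.files("ramansen.data").joinpath("table2_assignments.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def render_spectrum(
    source: CataboliteLineList | pd.DataFrame,
    grid: np.ndarray,
    fwhm: float = 10.0,
    shape: str = "lorentzian",
    scale_factor: float = 1.0,
) -> Spectrum:
    """Broaden a line list into a spectrum with unit-area line shapes, so the
    integral over the grid approaches the summed activity.

    ``scale_factor`` multiplies every line position (harmonic-frequency
    scaling knob; 1.0 by default since no scaling is applied upstream).
    """
    if fwhm <= 0:
        raise ValueError("FWHM must be > 0")
    grid = np.asarray(grid, dtype=float)
    if isinstance(source, CataboliteLineList):
        centers = np.array([l.wavenumber_cm1 for l in source.lines])
        acts = np.array([l.activity_A4_AMU for l in source.lines])
        name = source.name
    else:
        centers = source["wavenumber_cm1"].to_numpy(float)
        acts = source["activity_A4_AMU"].to_numpy(float)
        name = "table"
    centers = scale_factor * centers
    y = np.zeros_like(grid)
    if shape == "lorentzian":
        g = fwhm / 2.0
        for c, a in zip(centers, acts):
            y += a * (g / np.pi) / ((grid - c) ** 2 + g * g)
    elif shape == "gaussian":
        s = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        for c, a in zip(centers, acts):
            y += a * np.exp(-0.5 * ((grid - c) / s) ** 2) / (s * np.sqrt(2 * np.pi))
    else:
        raise ValueError(f"unknown line shape {shape!r}")
    return Spectrum(grid, y, {"sample_id": name, "map_id": "", "class_label": ""})


# ---------------------------------------------------------------------------
# Band grouping and experimental matching
# ---------------------------------------------------------------------------


def unique_bands(
    tables: list[pd.DataFrame], collision_tolerance: float = 2.0
) -> pd.DataFrame:
    """Group filtered peaks across catabolites into bands.

    Peaks whose wavenumbers lie within ``collision_tolerance`` of the running
    band are merged; each band carries its contributor catabolites and stages,
    and is flagged unique when any contributing row carries a spatially-unique
    annotation."""
    if not tables:
        raise ValueError("need at least one peak table")
    if collision_tolerance <= 0:
        raise ValueError("collision_tolerance must be > 0")
    rows = pd.concat(tables, ignore_index=True).sort_values("wavenumber_cm1")
    bands = []
    current: list[pd.Series] = []
    for _, row in rows.iterrows():
        if current and row["wavenumber_cm1"] - current[-1]["wavenumber_cm1"] > collision_tolerance:
            bands.append(current)
            current = []
        current.append(row)
    if current:
        bands.append(current)
    out = []
    for group in bands:
        wns = [r["wavenumber_cm1"] for r in group]
        out.append(
            {
                "wavenumber_cm1": float(np.mean(wns)),
                "contributors": sorted({r["catabolite"] for r in group}),
                "stages": sorted({r["stage"] for r in group}),
                "n_contributors": len({r["catabolite"] for r in group}),
                "spatially_unique": bool(
                    any(int(r.get("spatially_unique", 0)) for r in group)
                ),
            }
        )
    return pd.DataFrame(out)


def match_to_classes(
    bands: pd.DataFrame,
    class_peak_tables: dict[str, list[float]],
    tolerance: float = 3.0,
) -> pd.DataFrame:
    """Presence flag per senescence class for each candidate band: true when
    any experimental class peak lies within ``tolerance`` cm^-1."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    stage_rank = {s: i for i, s in enumerate(STAGES)}
    rows = []
    for _, band in bands.iterrows():
        rec = {
            "wavenumber_cm1": band["wavenumber_cm1"],
            "contributors": band["contributors"],
            "stages": band["stages"],
            "tolerance_cm1": tolerance,
            "earliest_stage": min(band["stages"], key=lambda s: stage_rank.get(s, 99)),
        }
        for cls, peaks in class_peak_tables.items():
            present = any(abs(p - band["wavenumber_cm1"]) <= tolerance for p in peaks)
            rec[f"present_{cls}"] = bool(present)
        rows.append(rec)
    return pd.DataFrame(rows)
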