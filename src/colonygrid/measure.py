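"""Per-cell colony quantification: Standard, Summation and Background modes.

Standard mode thresholds the image, finds connected particles, and assigns
each grid cell the area of the largest particle whose centroid falls inside
it — appropriate for robot-pinned colonies that grow as one round blob.
Summation mode sums *all* particle areas per cell (blunt-pin transfers that
shatter growth into fragments).  Background-Subtracted mode skips
thresholding altogether: it subtracts each cell's own corner-estimated
background gray level and reports the mean residual, which is what captures
density differences between equally-sized liquid-spotted colonies and makes
the measurement insensitive to slow lighting gradients across the plate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_isodata
from skimage.measure import label, regionprops

from .formats import MeasurementTable, LOG_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "Particle", "ParticleSet", "AnomalyParams", "QCResult",
    "threshold_binary", "find_particles", "detect_anomalies",
    "measure_standard", "measure_summation", "measure_background", "qc_check",
]


@dataclass(frozen=True)
class Particle:
    """One connected foreground component (a colony or an artifact)."""

    centroid: tuple[float, float]      # (x, y) in pixels
    area: float                        # pixel count
    circularity: float                 # 4*pi*area/perimeter^2, clamped to [0,1]
    label: int = 0
    cell_index: tuple[int, int] | None = None   # (row, col), 0-based


@dataclass
class ParticleSet:
    particles: list[Particle] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.particles)

    def __iter__(self):
        return iter(self.particles)

    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.particles], dtype=float)


@dataclass(frozen=True)
class AnomalyParams:
    """Artifact detection thresholds.

    A particle is an anomaly only when *both* hold: circularity below
    ``circularity_threshold`` (default 0.7) and area more than
    ``area_sd_threshold`` standard deviations (default 1.0) away from the
    plate's mean particle area.
    """

    circularity_threshold: float = 0.7
    area_sd_threshold: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.circularity_threshold < 1:
            raise ValueError("circularity_threshold must be in (0, 1)")
        if self.area_sd_threshold <= 0:
            raise ValueError("area_sd_threshold must be positive")


@dataclass(frozen=True)
class QCResult:
    """Quality control: particles assigned to cells vs. particles found.

    ``deviation`` is |total - assigned| / total; the plate passes when it
    does not exceed 25%.  A shattered threshold (many fragments per colony)
    or heavy debris both blow this ratio up.
    """

    assigned: int
    total_particles: int
    deviation: float
    passed: bool


def threshold_binary(image: np.ndarray) -> np.ndarray:
    """Automatic global threshold (isodata / iterative intermeans).

    Polarity is auto-detected so that colonies (the minority class) come out
    as foreground regardless of whether they scan brighter or darker than
    the agar.  A constant image yields an all-background mask and a warning.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if img.max() == img.min():
        warnings.warn("constant image: no threshold exists, returning empty mask")
        return np.zeros(img.shape, dtype=bool)
    t = threshold_isodata(img)
    mask = img > t
    if mask.mean() > 0.5:
        mask = ~mask
    return mask


def find_particles(binary: np.ndarray, min_area: int = 1) -> ParticleSet:
    """8-connected component analysis with centroid/area/circularity."""
    lab = label(np.asarray(binary, dtype=bool), connectivity=2)
    out = []
    for rp in regionprops(lab):
        if rp.area < min_area:
            continue
        # Crofton perimeter: near-exact for discs and ~2L for thin lines, so
        # circularity behaves like the classic shape descriptor (disc ~1,
        # line ~0); the marching-squares perimeter underestimates thin shapes
        perim = rp.perimeter_crofton
        circ = 4.0 * np.pi * rp.area / (perim * perim) if perim > 0 else 1.0
        cy, cx = rp.centroid
        out.append(Particle(
            centroid=(float(cx), float(cy)),
            area=float(rp.area),
            circularity=float(min(max(circ, 0.0), 1.0)),
            label=int(rp.label),
        ))
    return ParticleSet(out)


def detect_anomalies(particles: ParticleSet, params: AnomalyParams | None = None) -> list[Particle]:
    """Particles that are both non-circular and unusually sized.

    With fewer than two particles the plate SD is undefined; an empty list
    is returned with a warning.
    """
    params = params or AnomalyParams()
    if len(particles) < 2:
        warnings.warn("fewer than 2 particles: anomaly detection skipped")
        return []
    areas = particles.areas()
    mean, sd = areas.mean(), areas.std()
    if sd == 0:
        return []
    return [
        p for p in particles
        if p.circularity < params.circularity_threshold
        and abs(p.area - mean) > params.area_sd_threshold * sd
    ]


def qc_check(assigned: int, total: int) -> QCResult:
    """Pass iff |total - assigned| / total <= 0.25; total == 0 always fails."""
    if assigned < 0 or total < 0:
        raise ValueError("counts must be non-negative")
    if total == 0:
        return QCResult(assigned, total, deviation=1.0, passed=False)
    dev = abs(total - assigned) / total
    return QCResult(assigned, total, deviation=float(dev), passed=dev <= 0.25)


def _assign_cells(particles: ParticleSet, grid) -> list[Particle]:
    """Attach a 0-based (row, col) cell index to each particle by centroid."""
    out = []
    for p in particles:
        x, y = p.centroid
        idx = grid.cell_of(y, x)
        out.append(Particle(p.centroid, p.area, p.circularity, p.label, idx))
    return out


def _table(values: np.ndarray, plate_id: str, condition: str, mode: str) -> MeasurementTable:
    rows, cols = values.shape
    rec = {
        "plate": np.repeat(plate_id, rows * cols),
        "condition": np.repeat(condition, rows * cols),
        "row": np.repeat(np.arange(1, rows + 1), cols),
        "col": np.tile(np.arange(1, cols + 1), rows),
        "value": values.ravel(),
        "mode": np.repeat(mode, rows * cols),
    }
    return MeasurementTable(pd.DataFrame(rec, columns=LOG_COLUMNS + ["mode"]))


def _remove_listed(particles: ParticleSet, exclusions) -> ParticleSet:
    """Drop particles whose centroid is close to a listed (x, y) point.

    This replaces interactive artifact erasing: the anomaly report's
    centroids can be fed back verbatim to delete those particles.
    """
    if not exclusions:
        return particles
    pts = np.asarray([(float(x), float(y)) for x, y in exclusions])
    keep = []
    for p in particles:
        d = np.hypot(pts[:, 0] - p.centroid[0], pts[:, 1] - p.centroid[1])
        if d.min() > 2.0:
            keep.append(p)
    return ParticleSet(keep)


def measure_standard(
    image: np.ndarray,
    grid,
    plate_id: str = "plate",
    condition: str = "",
    params: AnomalyParams | None = None,
    exclusions: list[tuple[float, float]] | None = None,
) -> tuple[MeasurementTable, QCResult, list[Particle]]:
    """Largest-particle-per-cell measurement with QC and anomaly report.

    Returns (table, qc, anomalies).  Anomalies named in *exclusions*
    (centroid coordinates) are deleted before assignment; remaining detected
    anomalies are reported but still measured, mirroring a review-then-rerun
    workflow.  Cells with no particle get value 0.
    """
    mask = threshold_binary(image)
    particles = _remove_listed(find_particles(mask), exclusions)
    anomalies = detect_anomalies(particles, params) if len(particles) >= 2 else []
    assigned = _assign_cells(particles, grid)
    values = np.zeros(grid.format.shape)
    used = 0
    for p in assigned:
        if p.cell_index is None:
            continue
        r, c = p.cell_index
        if p.area > values[r, c]:
            if values[r, c] == 0:
                used += 1
            values[r, c] = p.area
    qc = qc_check(used, len(particles))
    return _table(values, plate_id, condition, "standard"), qc, anomalies


def measure_summation(
    image: np.ndarray, grid, plate_id: str = "plate", condition: str = ""
) -> MeasurementTable:
    """Sum of all particle areas per cell; no artifact handling by design."""
    mask = threshold_binary(image)
    particles = _assign_cells(find_particles(mask), grid)
    values = np.zeros(grid.format.shape)
    for p in particles:
        if p.cell_index is not None:
            r, c = p.cell_index
            values[r, c] += p.area
    return _table(values, plate_id, condition, "summation")


def measure_background(
    image: np.ndarray,
    grid,
    plate_id: str = "plate",
    condition: str = "",
    positive_only_mean: bool = False,
) -> MeasurementTable:
    """Corner-background-subtracted mean gray value per cell.

    The background of each cell is the median gray over four k x k corner
    patches (k = max(3, cell_side // 10)); the reported value is the mean of
    max(pixel - background, 0) over *all* cell pixels.  Set
    ``positive_only_mean=True`` to average only the positive residuals
    instead.
    """
    img = np.asarray(image, dtype=float)
    values = np.zeros(grid.format.shape)
    for r in range(grid.format.rows):
        for c in range(grid.format.cols):
            y0, x0, y1, x1 = grid.boxes[r][c]
            cell = img[y0:y1, x0:x1]
            k = max(3, min(cell.shape) // 10)
            corners = np.concatenate([
                cell[:k, :k].ravel(), cell[:k, -k:].ravel(),
                cell[-k:, :k].ravel(), cell[-k:, -k:].ravel(),
            ])
            bg = float(np.median(corners))
            resid = np.clip(cell - bg, 0.0, None)
            if positive_only_mean:
                pos = resid[resid > 0]
                values[r, c] = float(pos.mean()) if pos.size else 0.0
            else:
                values[r, c] = float(resid.mean())
    return _table(values, plate_id, condition, "background")
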