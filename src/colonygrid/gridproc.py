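"""Geometric plate processing: split, straighten, fine-crop, partition.

A multi-plate scan (plates tiled on a black scanner mask) is split into
rough crops; each rough crop is straightened so colony rows run horizontal,
then fine-cropped so the image border coincides with the colony grid
layout, validated, and symmetrically partitioned into one cell per colony.

The straightening estimate samples nine 3x3 squares of colony centroids
spread across the plate.  In a perfect square the diagonals run at 45/135
degrees and the edges at 0/90; the mean signed deviation of eight measured
angles per square from those ideals is the plate's rotation, and the mean
over squares is applied as the correction.

The fine crop mimics a rectangle walk: a band one pitch thick, spanning the
middle three-quarters of the plate, steps outward from the center until it
contains no colonies; the outermost colony pixel inside the walked region,
padded by half the inter-colony gap, becomes the border.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
from skimage.transform import rotate as _sk_rotate

from .errors import AlignmentError, ConfigError, CropError, SplitError
from .formats import GridFormat, write_log_file
from .measure import threshold_binary, find_particles

logger = logging.getLogger(__name__)

__all__ = [
    "PlateImage", "CellGrid", "split_multiplate", "estimate_rotation",
    "straighten", "estimate_pitch", "fine_crop", "validate_grid",
    "partition", "run_directory", "RunConfig",
]

MAX_STRAIGHTEN_ANGLE = 15.0


@dataclass
class PlateImage:
    """A grayscale plate raster plus pipeline metadata."""

    pixels: np.ndarray
    plate_id: str = "plate"
    condition: str = ""
    dpi: int = 300
    stage: str = "original"          # original | rough_crop | fine_crop
    crop_box: tuple[int, int, int, int] | None = None   # (y0, x0, y1, x1) in parent

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 3:                       # collapse RGB(A) scans
            px = px[..., :3].mean(axis=2)
        if px.size == 0:
            raise ValueError("empty raster")
        self.pixels = np.clip(px, 0, 255).astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class CellGrid:
    """rows x cols rectangular partition of a fine-cropped image.

    ``boxes[r][c]`` is (y0, x0, y1, x1) with half-open pixel bounds; the
    boxes tile the image exactly (remainder pixels go to the last rows and
    columns).
    """

    format: GridFormat
    boxes: list[list[tuple[int, int, int, int]]]
    row_edges: np.ndarray
    col_edges: np.ndarray
    colony_width: float = 0.0
    colony_gap: float = 0.0

    def cell_of(self, y: float, x: float) -> tuple[int, int] | None:
        """0-based (row, col) of the cell containing pixel (y, x), or None."""
        if not (self.row_edges[0] <= y < self.row_edges[-1]
                and self.col_edges[0] <= x < self.col_edges[-1]):
            return None
        r = int(np.searchsorted(self.row_edges, y, side="right") - 1)
        c = int(np.searchsorted(self.col_edges, x, side="right") - 1)
        return (r, c)


# ---------------------------------------------------------------------------
# multi-plate splitting

DARK_BACKGROUND_MAX = 20  # 8-bit gray at or below this counts as mask background


def split_multiplate(
    image: np.ndarray | PlateImage,
    arrangement: tuple[int, int] = (3, 3),
    plate_ids: list[str] | None = None,
    condition: str = "",
) -> list[PlateImage]:
    """Split a black-background composite scan into per-plate rough crops.

    Plates are located as large bright connected regions over the darkness
    threshold and returned in reading order (left-to-right, top-to-bottom).
    A detected plate count different from the declared arrangement raises
    :class:`SplitError`.
    """
    px = image.pixels if isinstance(image, PlateImage) else np.asarray(image)
    if px.ndim == 3:
        px = px[..., :3].mean(axis=2)
    pr, pc = arrangement
    expected = pr * pc

    from skimage.measure import label, regionprops
    bright = px > DARK_BACKGROUND_MAX
    lab = label(bright, connectivity=2)
    min_area = bright.size / (expected * 8)   # a plate fills >1/8 of its tile
    regions = [r for r in regionprops(lab) if r.area >= min_area]
    if len(regions) != expected:
        raise SplitError(
            f"detected {len(regions)} plates, expected {expected} "
            f"({pr}x{pc} arrangement)"
        )
    # reading order: cluster by centroid row band, then sort by column
    regions.sort(key=lambda r: r.centroid[0])
    rows = [regions[i * pc:(i + 1) * pc] for i in range(pr)]
    out = []
    k = 0
    for band in rows:
        band.sort(key=lambda r: r.centroid[1])
        for reg in band:
            y0, x0, y1, x1 = reg.bbox
            pid = plate_ids[k] if plate_ids else f"plate_{k + 1:02d}"
            out.append(PlateImage(px[y0:y1, x0:x1], plate_id=pid,
                                  condition=condition, stage="rough_crop"))
            k += 1
    return out


# ---------------------------------------------------------------------------
# rotation


def _colony_centroids(px: np.ndarray) -> np.ndarray:
    """(N, 2) array of (y, x) colony centroids from the thresholded image."""
    mask = threshold_binary(px)
    parts = find_particles(mask)
    if not len(parts):
        return np.empty((0, 2))
    areas = parts.areas()
    cutoff = max(4.0, 0.25 * float(np.median(areas)))
    return np.array([(p.centroid[1], p.centroid[0])
                     for p in parts if p.area >= cutoff])


def _square_deviation(pts: np.ndarray) -> float | None:
    """Mean signed angular deviation of a 3x3 centroid square from ideal.

    *pts* are 9 (y, x) points; returns None if they do not form a plausible
    3x3 block of adjacent grid positions.
    """
    order = np.argsort(pts[:, 0], kind="stable")
    rows = [pts[order[i * 3:(i + 1) * 3]] for i in range(3)]
    rows = [r[np.argsort(r[:, 1], kind="stable")] for r in rows]
    g = np.array(rows)          # g[row, col] = (y, x)

    # sanity: spacings along rows/cols must be consistent (one grid step)
    dx = np.diff(g[:, :, 1], axis=1).ravel()
    dy = np.diff(g[:, :, 0], axis=0).ravel()
    if dx.min() <= 0 or dy.min() <= 0:
        return None
    if dx.max() > 1.5 * dx.min() or dy.max() > 1.5 * dy.min():
        return None

    def ang(p, q):
        return np.degrees(np.arctan2(q[0] - p[0], q[1] - p[1]))

    # diagonals and the four outer edges of the square; the middle row and
    # column add no orientation information beyond these and are skipped
    measured = [
        (ang(g[0, 0], g[2, 2]), 45.0),    # main diagonal
        (ang(g[0, 2], g[2, 0]), 135.0),   # anti-diagonal
        (ang(g[0, 0], g[2, 0]), 90.0),    # left vertical edge
        (ang(g[0, 2], g[2, 2]), 90.0),    # right vertical edge
        (ang(g[0, 0], g[0, 2]), 0.0),     # top horizontal edge
        (ang(g[2, 0], g[2, 2]), 0.0),     # bottom horizontal edge
    ]
    devs = []
    for m, ideal in measured:
        d = ((m - ideal + 90.0) % 180.0) - 90.0
        devs.append(d)
    devs = np.asarray(devs)
    if np.abs(devs).max() > 12.0:
        return None
    return float(devs.mean())


def estimate_rotation(image: np.ndarray | PlateImage, fmt: GridFormat,
                      min_patches: int = 3) -> float:
    """Signed correction angle (degrees) that aligns colony rows horizontal.

    Nine 3x3 squares of colony centroids at symmetric positions across the
    grid are analyzed; fewer than ``min_patches`` usable squares raises
    :class:`AlignmentError`.  For an image rotated by theta the estimate is
    about -theta, i.e. ``straighten(image, estimate)`` aligns it.
    """
    px = image.pixels if isinstance(image, PlateImage) else np.asarray(image)
    cent = _colony_centroids(px)
    if len(cent) < 9:
        raise AlignmentError(f"only {len(cent)} colony centroids detected")
    lo = cent.min(axis=0)
    hi = cent.max(axis=0)
    devs = []
    for fy in (0.25, 0.5, 0.75):
        for fx in (0.25, 0.5, 0.75):
            target = lo + np.array([fy, fx]) * (hi - lo)
            # anchor the square on the colony nearest the patch position so
            # the 9 nearest centroids form a 3x3 block, not a diamond
            anchor = cent[np.argmin(np.hypot(*(cent - target).T))]
            d = np.hypot(*(cent - anchor).T)
            nearest = cent[np.argsort(d, kind="stable")[:9]]
            if len(nearest) < 9:
                continue
            dev = _square_deviation(nearest)
            if dev is not None:
                devs.append(dev)
    if len(devs) < min_patches:
        raise AlignmentError(
            f"only {len(devs)} valid 3x3 patches (need {min_patches})"
        )
    return float(np.mean(devs))


def _modal_border_value(px: np.ndarray) -> float:
    border = np.concatenate([px[0, :], px[-1, :], px[:, 0], px[:, -1]])
    vals, counts = np.unique(border, return_counts=True)
    return float(vals[np.argmax(counts)])


def straighten(image: np.ndarray | PlateImage, angle: float) -> PlateImage:
    """Rotate about the image center with bilinear interpolation.

    Corners exposed by the rotation are filled with the modal border gray.
    Angles beyond +/-15 degrees indicate gross misorientation and raise
    :class:`AlignmentError`.
    """
    if abs(angle) > MAX_STRAIGHTEN_ANGLE:
        raise AlignmentError(f"|angle| = {abs(angle):.1f} deg exceeds "
                             f"{MAX_STRAIGHTEN_ANGLE} deg")
    src = image if isinstance(image, PlateImage) else PlateImage(image)
    if angle == 0.0:
        return PlateImage(src.pixels.copy(), src.plate_id, src.condition,
                          src.dpi, src.stage)
    out = _sk_rotate(src.pixels.astype(float), angle, resize=False, order=1,
                     cval=_modal_border_value(src.pixels), preserve_range=True)
    return PlateImage(out, src.plate_id, src.condition, src.dpi, src.stage)


# ---------------------------------------------------------------------------
# pitch & fine crop


def _profile_pitch(profile: np.ndarray) -> tuple[float, float]:
    """(colony_width, pitch) from a foreground-sum profile via run lengths
    and autocorrelation."""
    if profile.max() <= 0:
        raise AlignmentError("no foreground in profile")
    # a disc's column-sum profile is a semicircle: the quarter-max width is
    # ~1.94 r, much closer to the true diameter than the half-max width
    binary = profile > 0.25 * profile.max()
    # mean run length of above-threshold stretches = colony width
    runs = []
    n = 0
    for b in binary:
        if b:
            n += 1
        elif n:
            runs.append(n)
            n = 0
    if n:
        runs.append(n)
    if not runs:
        raise AlignmentError("no colony runs in profile")
    width = float(np.mean(runs))

    f = profile - profile.mean()
    ac = np.correlate(f, f, mode="full")[len(f) - 1:]
    max_lag = min(len(ac) - 1, len(f) // 3)
    lo = max(3, int(width * 0.75))
    if max_lag <= lo + 1:
        raise AlignmentError("profile too short for pitch estimation")
    local_max = [
        k for k in range(lo, max_lag)
        if ac[k] >= ac[k - 1] and ac[k] >= ac[k + 1] and ac[k] > 0
    ]
    if not local_max:
        raise AlignmentError("no periodic structure detected")
    pitch = float(local_max[int(np.argmax([ac[k] for k in local_max]))])
    return width, pitch


def estimate_pitch(image: np.ndarray | PlateImage, fmt: GridFormat
                   ) -> tuple[float, float]:
    """(colony_width, colony_gap) in pixels of a straightened plate image."""
    px = image.pixels if isinstance(image, PlateImage) else np.asarray(image)
    mask = threshold_binary(px)
    if not mask.any():
        raise AlignmentError("blank image: no colonies detected")
    wx, px_pitch = _profile_pitch(mask.sum(axis=0).astype(float))
    wy, py_pitch = _profile_pitch(mask.sum(axis=1).astype(float))
    width = (wx + wy) / 2.0
    pitch = (px_pitch + py_pitch) / 2.0
    gap = pitch - width
    if gap <= 0:
        gap = max(1.0, pitch * 0.1)
    return width, gap


def _walk_border(occupied: np.ndarray, pitch: int, presence_min: float,
                 side: str) -> int:
    """Rectangle walk along one axis; returns the refined border coordinate.

    *occupied* is the foreground count per coordinate along the walk axis,
    already restricted to the central 3/4 band of the other axis.
    """
    n = len(occupied)
    center = n // 2
    step = max(2, pitch)

    def band_count(a: int) -> float:
        return float(occupied[max(0, a):max(0, a) + step].sum())

    # Bands clip at the image boundary; once a band lies fully outside it is
    # trivially empty, so an already fine-cropped image is a fixed point
    # (its border becomes the image edge).
    if side == "low":
        a = center - step // 2
        while band_count(a) > presence_min:
            a -= step
            if a + step <= 0:
                a = -step                     # fully outside: empty
                break
        interior = max(0, a + step)           # interior edge of empty band
        # outermost foreground pixel at/after the interior edge
        idx = np.nonzero(occupied[interior:] > 0)[0]
        if idx.size == 0:
            raise CropError("no foreground inside walked region")
        return interior + int(idx[0])
    else:
        a = center - step // 2
        while band_count(a) > presence_min:
            a += step
            if a >= n:
                break                         # fully outside: empty
        interior = min(n, a)                  # interior edge of empty band
        idx = np.nonzero(occupied[:interior] > 0)[0]
        if idx.size == 0:
            raise CropError("no foreground inside walked region")
        return int(idx[-1]) + 1


def fine_crop(image: np.ndarray | PlateImage, fmt: GridFormat) -> PlateImage:
    """Crop a straightened rough crop to its colony grid layout.

    The border on each side is the outermost colony pixel found by the
    rectangle walk, padded outward by half the inter-colony gap so that the
    resulting image partitions into centered cells.
    """
    src = image if isinstance(image, PlateImage) else PlateImage(image)
    px = src.pixels
    mask = threshold_binary(px)
    if not mask.any():
        raise CropError("blank image: nothing to crop")
    width, gap = estimate_pitch(src, fmt)
    pitch = int(round(width + gap))
    presence_min = max(4.0, 0.15 * np.pi * (width / 2.0) ** 2)

    h, w = mask.shape
    bandy = slice(int(h * 0.125), int(h * 0.875))
    bandx = slice(int(w * 0.125), int(w * 0.875))
    col_occ = mask[bandy, :].sum(axis=0).astype(float)   # per x coordinate
    row_occ = mask[:, bandx].sum(axis=1).astype(float)   # per y coordinate

    left = _walk_border(col_occ, pitch, presence_min, "low")
    right = _walk_border(col_occ, pitch, presence_min, "high")
    top = _walk_border(row_occ, pitch, presence_min, "low")
    bottom = _walk_border(row_occ, pitch, presence_min, "high")

    pad = gap / 2.0
    y0 = max(0, int(round(top - pad)))
    y1 = min(h, int(round(bottom + pad)))
    x0 = max(0, int(round(left - pad)))
    x1 = min(w, int(round(right + pad)))
    if y1 - y0 < fmt.rows or x1 - x0 < fmt.cols:
        raise CropError("crop region collapsed below one pixel per cell")
    return PlateImage(px[y0:y1, x0:x1], src.plate_id, src.condition,
                      src.dpi, "fine_crop", crop_box=(y0, x0, y1, x1))


def partition(image: np.ndarray | PlateImage, fmt: GridFormat,
              colony_width: float = 0.0, colony_gap: float = 0.0) -> CellGrid:
    """Symmetric partition into rows x cols congruent cells.

    Integer remainders are absorbed by the last rows/columns (one extra
    pixel each), so the union of boxes is exactly the image area.
    """
    px = image.pixels if isinstance(image, PlateImage) else np.asarray(image)
    h, w = px.shape[:2]
    if h < fmt.rows or w < fmt.cols:
        raise ValueError(f"image {h}x{w} smaller than grid {fmt.rows}x{fmt.cols}")

    def edges(extent: int, n: int) -> np.ndarray:
        base, rem = divmod(extent, n)
        sizes = [base] * (n - rem) + [base + 1] * rem
        return np.concatenate([[0], np.cumsum(sizes)])

    rows_e = edges(h, fmt.rows)
    cols_e = edges(w, fmt.cols)
    boxes = [
        [(int(rows_e[r]), int(cols_e[c]), int(rows_e[r + 1]), int(cols_e[c + 1]))
         for c in range(fmt.cols)]
        for r in range(fmt.rows)
    ]
    return CellGrid(fmt, boxes, rows_e, cols_e, colony_width, colony_gap)


def validate_grid(image: np.ndarray | PlateImage, fmt: GridFormat,
                  line_fg_tol: float = 0.10, line_fail_tol: float = 0.05) -> bool:
    """Check that inter-row/inter-column separator lines avoid colonies.

    A separator line fails if more than ``line_fg_tol`` of its pixels are
    foreground; the plate fails if more than ``line_fail_tol`` of all lines
    fail.  A blank plate trivially passes.
    """
    px = image.pixels if isinstance(image, PlateImage) else np.asarray(image)
    mask = threshold_binary(px)
    if not mask.any():
        return True
    grid = partition(px, fmt)
    failed = 0
    n_lines = 0
    for e in grid.row_edges[1:-1]:
        n_lines += 1
        if mask[int(e), :].mean() > line_fg_tol:
            failed += 1
    for e in grid.col_edges[1:-1]:
        n_lines += 1
        if mask[:, int(e)].mean() > line_fg_tol:
            failed += 1
    return failed <= line_fail_tol * n_lines


# ---------------------------------------------------------------------------
# directory workflow

STAGE_DIRS = ["original_scans", "rough_crops", "fine_crops",
              "fine_crop_errors", "measurements_passed", "measurement_errors"]

IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".gif"}


@dataclass
class RunConfig:
    """Parameters of one directory-processing run."""

    format: GridFormat
    mode: str = "standard"               # standard | summation | background
    layout: str = "auto"                 # auto | multi | rough | fine
    arrangement: tuple[int, int] = (3, 3)
    log_name: str = "colony_log.tsv"
    condition_split: str = "_"           # filename stem: <condition><sep><batch>

    def __post_init__(self) -> None:
        if self.mode not in ("standard", "summation", "background"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.layout not in ("auto", "multi", "rough", "fine"):
            raise ConfigError(f"unknown layout {self.layout!r}")


def _list_images(d: Path) -> list[Path]:
    if not d.is_dir():
        return []
    return sorted(p for p in d.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)


def _detect_layout(parent: Path) -> str:
    if _list_images(parent / "fine_crops"):
        return "fine"
    if _list_images(parent / "rough_crops"):
        return "rough"
    if _list_images(parent):
        return "multi"
    raise ConfigError(f"no images found under {parent}")


def _parse_name(stem: str, sep: str) -> tuple[str, str]:
    """(condition, rest) from a filename stem like 'treated_b1' or
    'treated_b1_03'; the condition label must not contain the separator."""
    if sep in stem:
        cond, rest = stem.split(sep, 1)
        return cond, rest
    return stem, "b1"


def run_directory(parent_dir: str | Path, config: RunConfig) -> dict:
    """Process a directory tree of plate images through the full pipeline.

    Images are copied (never destructively moved) through the stage folders
    ``original_scans -> rough_crops -> fine_crops -> measurements_passed``,
    with failures landing in ``fine_crop_errors`` or ``measurement_errors``.
    Measurements append to the run's log file; a re-run picks up images that
    sit in ``fine_crops`` but have not been measured yet and writes them to
    a new, suffixed log file.  Returns a status manifest (also written as
    ``run_status.json``).
    """
    from .measure import measure_standard, measure_summation, measure_background

    parent = Path(parent_dir)
    if not parent.is_dir():
        raise ConfigError(f"{parent} is not a directory")
    layout = config.layout if config.layout != "auto" else _detect_layout(parent)

    for d in STAGE_DIRS:
        (parent / d).mkdir(exist_ok=True)

    status: dict[str, dict] = {}
    manifest_path = parent / "run_status.json"
    previous = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    measured_before = {k for k, v in previous.items() if v.get("status") == "measured"}

    # stage 1: multi-plate split
    if layout == "multi":
        for f in _list_images(parent):
            shutil.copy2(f, parent / "original_scans" / f.name)
            cond, batch = _parse_name(f.stem, config.condition_split)
            img = iio.imread(f)
            pr, pc = config.arrangement
            pids = [f"{batch}_{k + 1:02d}" for k in range(pr * pc)]
            try:
                plates = split_multiplate(img, config.arrangement, pids, cond)
            except SplitError as e:
                status[f.name] = {"status": "split_error", "detail": str(e)}
                continue
            for p in plates:
                name = f"{cond}{config.condition_split}{p.plate_id}.png"
                iio.imwrite(parent / "rough_crops" / name, p.pixels)
                status[name] = {"status": "rough_crop", "plate": p.plate_id,
                                "condition": cond}
    elif layout == "rough":
        for f in _list_images(parent):
            shutil.copy2(f, parent / "rough_crops" / f.name)

    # stage 2: straighten + fine crop
    if layout in ("multi", "rough"):
        for f in _list_images(parent / "rough_crops"):
            out_name = f.name
            if (parent / "fine_crops" / out_name).exists():
                continue
            img = iio.imread(f)
            try:
                angle = estimate_rotation(img, config.format)
                st = straighten(img, float(np.clip(angle, -MAX_STRAIGHTEN_ANGLE,
                                                   MAX_STRAIGHTEN_ANGLE)))
                fc = fine_crop(st, config.format)
                if not validate_grid(fc, config.format):
                    raise CropError("grid validation failed after crop")
            except (AlignmentError, CropError) as e:
                shutil.copy2(f, parent / "fine_crop_errors" / f.name)
                status[f.name] = {"status": "fine_crop_error", "detail": str(e)}
                continue
            iio.imwrite(parent / "fine_crops" / out_name, fc.pixels)
            status[out_name] = {"status": "fine_crop"}
    elif layout == "fine":
        for f in _list_images(parent):
            shutil.copy2(f, parent / "fine_crops" / f.name)

    # stage 3: measurement
    to_measure = [f for f in _list_images(parent / "fine_crops")
                  if f.name not in measured_before]
    rerun = bool(measured_before)
    log_path = parent / config.log_name
    if rerun and log_path.exists():
        stem, suffix = log_path.stem, log_path.suffix
        k = 1
        while (parent / f"{stem}.rerun{k}{suffix}").exists():
            k += 1
        log_path = parent / f"{stem}.rerun{k}{suffix}"

    for f in to_measure:
        cond, pid = _parse_name(f.stem, config.condition_split)
        img = iio.imread(f)
        grid = partition(img, config.format)
        try:
            if config.mode == "standard":
                table, qc, anomalies = measure_standard(img, grid, pid, cond)
                if not qc.passed:
                    shutil.copy2(f, parent / "measurement_errors" / f.name)
                    status[f.name] = {
                        "status": "measurement_error",
                        "detail": f"QC deviation {qc.deviation:.3f} > 0.25",
                    }
                    continue
                extra = {"qc_deviation": qc.deviation, "anomalies": len(anomalies)}
            elif config.mode == "summation":
                table = measure_summation(img, grid, pid, cond)
                extra = {}
            else:
                table = measure_background(img, grid, pid, cond)
                extra = {}
        except Exception as e:   # defensive: any failure routes to errors
            shutil.copy2(f, parent / "measurement_errors" / f.name)
            status[f.name] = {"status": "measurement_error", "detail": str(e)}
            continue
        write_log_file(table, log_path, append=True)
        shutil.copy2(f, parent / "measurements_passed" / f.name)
        status[f.name] = {"status": "measured", "log": log_path.name, **extra}

    merged = {**previous, **status}
    manifest_path.write_text(json.dumps(merged, indent=1, sort_keys=True))
    return {"layout": layout, "log": str(log_path), "status": merged}
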