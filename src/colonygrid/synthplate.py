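"""Ground-truthed synthetic plate images and whole synthetic screens.

Real scans of gridded agar plates come in three flavours depending on how
cells were deposited: robot-pinned discrete colonies (continuous round
colonies whose *area* encodes growth), blunt-pin transfers (each position
grows as several non-contiguous fragments) and liquid-spotted cultures
(equal-area spots whose *density* encodes growth).  :func:`generate_plate`
emulates all three, plus the nuisance factors that the geometric pipeline
must survive: plate rotation, additive background gradients, Gaussian pixel
noise and linear scratch artifacts.  Every image is returned together with
an exact :class:`GroundTruth` so downstream measurements can be scored.

:func:`generate_screen` assembles full control/experimental screens as
multi-plate composites on a black background (the scanner-mask layout) with
a matching key file and a truth table of planted effect ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio
from skimage.transform import rotate as _sk_rotate

from .errors import ConfigError
from .formats import GridFormat, FORMAT_384, PlateKey, write_key_file

__all__ = [
    "PlateSpec", "GroundTruth", "ScreenSpec",
    "generate_plate", "generate_screen", "simulate_null_ratios",
]


@dataclass
class PlateSpec:
    """Everything needed to render one synthetic plate deterministically.

    ``colony_radius`` may be a scalar or a per-position (rows x cols) array;
    radius 0 means the position is empty.  ``colony_gray`` likewise accepts a
    per-position array, which is how density differences (liquid-spotted
    plates) are encoded.  ``seed`` fixes all randomness.
    """

    format: GridFormat = FORMAT_384
    pitch: float = 24.0
    colony_radius: float | np.ndarray = 8.0
    colony_gray: float | np.ndarray = 180.0
    agar_gray: float = 60.0
    rotation: float = 0.0
    noise_sd: float = 0.0
    gradient: tuple[float, float] = (0.0, 0.0)
    margin: float | None = None          # default: one pitch
    deposition: str = "pinned"           # pinned | fragmented | spotted
    n_fragments: int = 5
    artifacts: list[dict] = field(default_factory=list)
    seed: int = 0

    def radius_map(self) -> np.ndarray:
        r = np.asarray(self.colony_radius, dtype=float)
        if r.ndim == 0:
            r = np.full(self.format.shape, float(r))
        if r.shape != self.format.shape:
            raise ConfigError(f"radius map shape {r.shape} != {self.format.shape}")
        if (r < 0).any():
            raise ConfigError("colony radii must be >= 0")
        return r

    def gray_map(self) -> np.ndarray:
        g = np.asarray(self.colony_gray, dtype=float)
        if g.ndim == 0:
            g = np.full(self.format.shape, float(g))
        if g.shape != self.format.shape:
            raise ConfigError(f"gray map shape {g.shape} != {self.format.shape}")
        return g


@dataclass
class GroundTruth:
    """Exact per-position truth for a generated plate.

    ``area`` is the pixel count of each colony's rendered footprint
    (coverage >= 0.5) before rotation/noise.  ``density`` is the expected
    background-subtracted mean gray of each cell.  ``bbox`` is the grid
    layout box (tight colony extent expanded by half the inter-colony gap on
    each side) as (top, left, bottom, right) pixel coordinates in the
    unrotated frame — the target of a correct fine crop.
    """

    area: np.ndarray
    density: np.ndarray
    centers: np.ndarray            # (rows, cols, 2) [y, x]
    bbox: tuple[float, float, float, float]
    rotation: float
    colony_width: float
    colony_gap: float
    artifacts: list[dict]


def _render_disc(canvas: np.ndarray, cy: float, cx: float, r: float) -> np.ndarray:
    """Add an anti-aliased disc's coverage (in [0,1] per pixel) to *canvas*."""
    if r <= 0:
        return canvas
    y0, y1 = int(max(0, np.floor(cy - r - 1))), int(min(canvas.shape[0], np.ceil(cy + r + 2)))
    x0, x1 = int(max(0, np.floor(cx - r - 1))), int(min(canvas.shape[1], np.ceil(cx + r + 2)))
    if y0 >= y1 or x0 >= x1:
        return canvas
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(yy + 0.5 - cy, xx + 0.5 - cx)
    cov = np.clip(r + 0.5 - d, 0.0, 1.0)
    np.maximum(canvas[y0:y1, x0:x1], cov, out=canvas[y0:y1, x0:x1])
    return canvas


def _draw_line(canvas: np.ndarray, p0: tuple[float, float], p1: tuple[float, float],
               width: float) -> None:
    """Coverage of a thick line segment from p0 to p1 ((y, x) coords)."""
    y0a, x0a = p0
    y1a, x1a = p1
    n = int(max(abs(y1a - y0a), abs(x1a - x0a), 1) * 2)
    for t in np.linspace(0.0, 1.0, n):
        _render_disc(canvas, y0a + t * (y1a - y0a), x0a + t * (x1a - x0a), width / 2.0)


def generate_plate(spec: PlateSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one plate and its exact ground truth.

    Raises :class:`ConfigError` if colonies would overlap at the requested
    pitch/radius.
    """
    fmt = spec.format
    rng = np.random.default_rng(spec.seed)
    radii = spec.radius_map()
    grays = spec.gray_map()
    if 2 * radii.max() >= spec.pitch:
        raise ConfigError(
            f"colony diameter {2 * radii.max():.1f} exceeds pitch {spec.pitch}"
        )
    margin = spec.pitch if spec.margin is None else spec.margin
    h = int(round(fmt.rows * spec.pitch + 2 * margin))
    w = int(round(fmt.cols * spec.pitch + 2 * margin))

    img = np.full((h, w), float(spec.agar_gray))
    centers = np.zeros((fmt.rows, fmt.cols, 2))
    area = np.zeros(fmt.shape)
    density = np.zeros(fmt.shape)
    cell_px = spec.pitch * spec.pitch

    half = int(np.ceil(spec.pitch / 2)) + 1
    for i in range(fmt.rows):
        for j in range(fmt.cols):
            cy = margin + (i + 0.5) * spec.pitch
            cx = margin + (j + 0.5) * spec.pitch
            centers[i, j] = (cy, cx)
            r = radii[i, j]
            if r <= 0:
                continue
            # colonies never overlap (pitch check above), so each renders
            # into its own local patch around the cell
            y0 = max(0, int(cy) - half)
            x0 = max(0, int(cx) - half)
            cov = np.zeros((min(h, int(cy) + half) - y0,
                            min(w, int(cx) + half) - x0))
            if spec.deposition == "fragmented":
                # split the footprint into n disjoint fragments of equal
                # total area, arranged on a jittered ring inside the cell so
                # blunt-pin growth stays non-contiguous
                k = max(1, spec.n_fragments)
                rf = r / np.sqrt(k)
                ring = max(0.0, min(2 * rf + 1, spec.pitch / 2 - rf - 1.5))
                phase = rng.uniform(0, 2 * np.pi)
                for q in range(k):
                    ang = phase + 2 * np.pi * (q + rng.uniform(-0.1, 0.1)) / k
                    off = ring * rng.uniform(0.9, 1.0) if k > 1 else 0.0
                    _render_disc(cov, cy - y0 + off * np.sin(ang),
                                 cx - x0 + off * np.cos(ang), rf)
            else:
                _render_disc(cov, cy - y0, cx - x0, r)
            area[i, j] = int((cov >= 0.5).sum())
            density[i, j] = (grays[i, j] - spec.agar_gray) * cov.sum() / cell_px
            img[y0:y0 + cov.shape[0], x0:x0 + cov.shape[1]] += \
                cov * (grays[i, j] - spec.agar_gray)

    for art in spec.artifacts:
        cov = np.zeros_like(img)
        kind = art.get("kind", "line")
        gray = art.get("gray", float(np.max(grays)))
        if kind == "line":
            _draw_line(cov, art["start"], art["end"], art.get("width", 3.0))
        elif kind == "blob":
            _render_disc(cov, art["center"][0], art["center"][1], art["radius"])
        else:
            raise ConfigError(f"unknown artifact kind {kind!r}")
        img = img + cov * (gray - spec.agar_gray)

    # grid layout bbox: tight colony extent + half a gap of margin per side
    width_nom = 2 * float(np.median(radii[radii > 0])) if (radii > 0).any() else 0.0
    gap = spec.pitch - width_nom
    occ = radii > 0
    if occ.any():
        ys = centers[..., 0][occ]
        xs = centers[..., 1][occ]
        rs = radii[occ]
        top = (ys - rs).min() - gap / 2
        left = (xs - rs).min() - gap / 2
        bottom = (ys + rs).max() + gap / 2
        right = (xs + rs).max() + gap / 2
    else:
        top = left = 0.0
        bottom, right = float(h), float(w)

    gy, gx = spec.gradient
    if gy or gx:
        yy, xx = np.mgrid[0:h, 0:w]
        img = img + gy * yy + gx * xx
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    if spec.rotation != 0.0:
        img = _sk_rotate(img, spec.rotation, resize=False, order=1,
                         cval=float(spec.agar_gray), preserve_range=True)
    img = np.clip(img, 0, 255).astype(np.uint8)

    truth = GroundTruth(
        area=area, density=density, centers=centers,
        bbox=(float(top), float(left), float(bottom), float(right)),
        rotation=spec.rotation, colony_width=width_nom, colony_gap=gap,
        artifacts=list(spec.artifacts),
    )
    return img, truth


# ---------------------------------------------------------------------------
# whole screens


@dataclass
class ScreenSpec:
    """A control/experimental screen rendered as multi-plate composites.

    ``planted_ratios`` maps strain id -> experimental/control growth ratio
    (area ratio).  Unlisted strains get ratio 1.  ``growth_cv`` is the
    coefficient of variation of colony areas around their nominal value,
    emulating pinning variability.
    """

    format: GridFormat = FORMAT_384
    arrangement: tuple[int, int] = (3, 3)
    n_batches: int = 1
    conditions: tuple[str, ...] = ("control", "treated")
    control_condition: str = "control"
    pitch: float = 24.0
    # base radius leaves headroom below the overlap limit (pitch/2 - 1.5) so
    # planted suppressors can express up to ~3x area growth without clipping
    base_radius: float = 6.0
    colony_gray: float = 180.0
    agar_gray: float = 60.0
    growth_cv: float = 0.05
    planted_ratios: dict[str, float] = field(default_factory=dict)
    rotation_sd: float = 0.0
    noise_sd: float = 2.0
    seed: int = 0

    @property
    def plates_per_batch(self) -> int:
        return self.arrangement[0] * self.arrangement[1]


def _strain_grid(fmt: GridFormat, plate_id: str) -> tuple[np.ndarray, np.ndarray]:
    """Strain/orf id arrays; quad layouts share one strain per 2x2 block."""
    strains = np.empty(fmt.shape, dtype=object)
    orfs = np.empty(fmt.shape, dtype=object)
    for i in range(fmt.rows):
        for j in range(fmt.cols):
            if fmt.replicate_layout == "quad_2x2":
                bi, bj = i // 2, j // 2
                sid = f"{plate_id}_s{bi * (fmt.cols // 2) + bj + 1:04d}"
            else:
                sid = f"{plate_id}_s{i * fmt.cols + j + 1:04d}"
            strains[i, j] = sid
            orfs[i, j] = "ORF" + sid.split("_s")[-1]
    return strains, orfs


def compose_multiplate(plates: list[np.ndarray], arrangement: tuple[int, int],
                       gap: int = 40) -> np.ndarray:
    """Tile plate images onto a black background in reading order."""
    pr, pc = arrangement
    if len(plates) != pr * pc:
        raise ConfigError(f"{len(plates)} plates for a {pr}x{pc} arrangement")
    ph = max(p.shape[0] for p in plates)
    pw = max(p.shape[1] for p in plates)
    canvas = np.zeros((pr * ph + (pr + 1) * gap, pc * pw + (pc + 1) * gap), dtype=np.uint8)
    for k, p in enumerate(plates):
        r, c = divmod(k, pc)
        y = gap + r * (ph + gap)
        x = gap + c * (pw + gap)
        canvas[y:y + p.shape[0], x:x + p.shape[1]] = p
    return canvas


def generate_screen(spec: ScreenSpec, out_dir: str | Path) -> dict:
    """Write a full synthetic screen to *out_dir* and return its manifest.

    Produces one multi-plate composite per (condition, batch) named
    ``<condition>_b<batch>.png``, a ``key.tsv`` covering every plate and a
    ``truth.tsv`` listing each strain's planted experimental/control ratio.
    Deterministic for a fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    fmt = spec.format

    key_rows = []
    truth_rows = []
    manifest: dict = {"images": [], "plates": []}

    for b in range(1, spec.n_batches + 1):
        plate_ids = [f"b{b}_{k + 1:02d}" for k in range(spec.plates_per_batch)]
        # nominal control areas per position (shared across conditions so the
        # planted ratio is the only systematic difference)
        base = {}
        ratio_grid = {}
        for pid in plate_ids:
            strains, orfs = _strain_grid(fmt, pid)
            a0 = np.pi * spec.base_radius ** 2 * rng.lognormal(
                0.0, 0.05, fmt.shape
            )
            base[pid] = a0
            ratios = np.ones(fmt.shape)
            for i in range(fmt.rows):
                for j in range(fmt.cols):
                    ratios[i, j] = spec.planted_ratios.get(strains[i, j], 1.0)
            ratio_grid[pid] = ratios
            for i in range(fmt.rows):
                for j in range(fmt.cols):
                    key_rows.append((pid, i + 1, j + 1, strains[i, j], orfs[i, j], 0))
            seen = set()
            for i in range(fmt.rows):
                for j in range(fmt.cols):
                    s = strains[i, j]
                    if s in seen:
                        continue
                    seen.add(s)
                    truth_rows.append((s, spec.planted_ratios.get(s, 1.0)))

        for cond in spec.conditions:
            plates = []
            for pid in plate_ids:
                mult = np.ones(fmt.shape) if cond == spec.control_condition \
                    else ratio_grid[pid]
                areas = base[pid] * mult * rng.lognormal(
                    0.0, spec.growth_cv, fmt.shape
                )
                radii = np.sqrt(areas / np.pi)
                radii = np.minimum(radii, spec.pitch / 2 - 1.5)
                rot = rng.normal(0.0, spec.rotation_sd) if spec.rotation_sd else 0.0
                pspec = PlateSpec(
                    format=fmt, pitch=spec.pitch, colony_radius=radii,
                    colony_gray=spec.colony_gray, agar_gray=spec.agar_gray,
                    rotation=float(np.clip(rot, -10, 10)), noise_sd=spec.noise_sd,
                    seed=int(rng.integers(0, 2 ** 31 - 1)),
                )
                img, _ = generate_plate(pspec)
                plates.append(img)
                manifest["plates"].append({"plate": pid, "condition": cond})
            composite = compose_multiplate(plates, spec.arrangement)
            name = f"{cond}_b{b}.png"
            iio.imwrite(out_dir / name, composite)
            manifest["images"].append(name)

    key_df = PlateKey(
        pd.DataFrame(
            key_rows, columns=["plate", "row", "col", "strain", "orf", "control"]
        )
    )
    write_key_file(key_df, out_dir / "key.tsv")
    pd.DataFrame(truth_rows, columns=["strain", "planted_ratio"]).to_csv(
        out_dir / "truth.tsv", sep="\t", index=False, lineterminator="\n"
    )
    manifest["key"] = "key.tsv"
    manifest["truth"] = "truth.tsv"
    return manifest


def simulate_null_ratios(
    n_strains: int, n_replicates: int = 4, cv: float = 0.1, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Numbers-only null screen: control and experimental replicate values
    drawn from the same lognormal distribution (no true effects).

    Returns two (n_strains, n_replicates) arrays of normalized growth
    values. Used for statistical calibration without rendering images.
    """
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv ** 2))
    ctrl = rng.lognormal(0.0, sigma, (n_strains, n_replicates))
    exp = rng.lognormal(0.0, sigma, (n_strains, n_replicates))
    return ctrl, exp
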