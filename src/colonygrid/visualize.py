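"""Plate cartoons: normalized-growth renderings and control/experimental
comparisons with statistics overlaid.

Each colony is drawn as a circle whose radius and fill both encode its
normalized growth: light gray for small colonies, black at the plate median,
shading into blue above it.  Highlight halos mark review states — yellow for
low growth (< 25% of the median), red for excluded positions on single-plate
renders; on comparison renders green marks strains with excluded replicates,
orange strains dead on both plates, red statistically significant strains.
Output is deterministic SVG text (optionally rasterized to PNG via
matplotlib), plus a machine-readable legend TSV replacing the original
hover interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CartoonStyle", "render_plate", "render_comparison", "export_selection",
           "svg_to_png"]


@dataclass(frozen=True)
class CartoonStyle:
    cell_px: int = 18
    radius_cap: float = 2.0        # max circle radius in plate-median units
    low_color: str = "#d3d3d3"     # small colonies
    median_color: str = "#000000"  # at the plate median
    high_color: str = "#1040ff"    # above the median
    low_growth_halo: str = "#ffe45c"
    excluded_halo: str = "#ff5c5c"
    dead_both_halo: str = "#ff9a28"
    excluded_cmp_halo: str = "#35c06b"
    significant_halo: str = "#ff5c5c"
    background: str = "#ffffff"


def _lerp(c0: str, c1: str, t: float) -> str:
    a = np.array([int(c0[i:i + 2], 16) for i in (1, 3, 5)], dtype=float)
    b = np.array([int(c1[i:i + 2], 16) for i in (1, 3, 5)], dtype=float)
    v = np.clip(a + (b - a) * np.clip(t, 0.0, 1.0), 0, 255).astype(int)
    return "#{:02x}{:02x}{:02x}".format(*v)


def colony_color(value: float, style: CartoonStyle) -> str:
    """Light gray -> black on [0, 1], black -> blue on [1, 2] (clamped)."""
    if not np.isfinite(value):
        return style.low_color
    if value <= 1.0:
        return _lerp(style.low_color, style.median_color, value)
    return _lerp(style.median_color, style.high_color, (value - 1.0))


def colony_radius(value: float, style: CartoonStyle) -> float:
    """Radius monotone in value, capped so giants don't overlap neighbors."""
    v = min(max(value, 0.0) if np.isfinite(value) else 0.0, style.radius_cap)
    ref = 0.35 * style.cell_px          # radius at the plate median
    return ref * v / 1.0 if v <= style.radius_cap else ref * style.radius_cap


def _svg_header(w: int, h: int, style: CartoonStyle) -> list[str]:
    return [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w}" height="{h}" '
        f'viewBox="0 0 {w} {h}">',
        f'<rect width="{w}" height="{h}" fill="{style.background}"/>',
    ]


def _plate_elements(values: np.ndarray, halos: np.ndarray | None,
                    style: CartoonStyle, ox: float = 0, oy: float = 0) -> list[str]:
    rows, cols = values.shape
    out = []
    s = style.cell_px
    for r in range(rows):
        for c in range(cols):
            cx = ox + (c + 0.5) * s
            cy = oy + (r + 0.5) * s
            if halos is not None and halos[r, c]:
                out.append(
                    f'<rect x="{ox + c * s:.1f}" y="{oy + r * s:.1f}" '
                    f'width="{s}" height="{s}" fill="{halos[r, c]}"/>'
                )
            v = values[r, c]
            rad = colony_radius(v, style)
            if rad <= 0:
                continue
            out.append(
                f'<circle cx="{cx:.1f}" cy="{cy:.1f}" r="{rad:.2f}" '
                f'fill="{colony_color(v, style)}"/>'
            )
    return out


def _halo_grid(shape, low_growth, excluded, style: CartoonStyle) -> np.ndarray:
    """Excluded (red) takes precedence over low-growth (yellow)."""
    halos = np.full(shape, "", dtype=object)
    if low_growth is not None:
        halos[np.asarray(low_growth, dtype=bool)] = style.low_growth_halo
    if excluded is not None:
        halos[np.asarray(excluded, dtype=bool)] = style.excluded_halo
    return halos


def render_plate(values: np.ndarray, low_growth: np.ndarray | None = None,
                 excluded: np.ndarray | None = None,
                 style: CartoonStyle | None = None,
                 path: str | Path | None = None) -> str:
    """Single-plate cartoon of normalized values with review highlights.

    Returns the SVG text; also writes it to *path* when given.  Re-rendering
    identical inputs yields byte-identical output.
    """
    style = style or CartoonStyle()
    values = np.asarray(values, dtype=float)
    halos = _halo_grid(values.shape, low_growth, excluded, style)
    rows, cols = values.shape
    w, h = cols * style.cell_px, rows * style.cell_px
    parts = _svg_header(w, h, style)
    parts += _plate_elements(values, halos, style)
    parts.append("</svg>")
    svg = "\n".join(parts) + "\n"
    if path is not None:
        Path(path).write_text(svg)
    return svg


#: comparison highlight precedence, strongest first
COMPARISON_PRECEDENCE = ("excluded", "dead_both", "significant")


def _strain_state(row: pd.Series, p_threshold: float) -> str:
    if row.get("excluded_count", 0) and row["excluded_count"] > 0:
        return "excluded"
    cm = row.get("control_mean", np.nan)
    em = row.get("experimental_mean", np.nan)
    if cm == 0 and em == 0:
        return "dead_both"
    p = row.get("p_adjusted", np.nan)
    if np.isfinite(p) and p < p_threshold:
        return "significant"
    return ""


def render_comparison(
    control_values: np.ndarray,
    experimental_values: np.ndarray,
    stats: pd.DataFrame,
    position_strain: np.ndarray,
    p_threshold: float = 0.05,
    style: CartoonStyle | None = None,
    out_prefix: str | Path | None = None,
) -> tuple[str, pd.DataFrame]:
    """Side-by-side control/experimental cartoon for one condition.

    ``position_strain`` is a rows x cols array of strain ids mapping grid
    positions to rows of *stats*.  Strain highlight states follow the
    documented precedence (excluded > dead-on-both > significant); raising
    the p threshold only ever adds red highlights.  Returns the SVG text and
    the legend table (one row per highlighted strain with position, ORF,
    p-value, z-score and growth ratios); with *out_prefix*, writes
    ``<prefix>.svg`` and ``<prefix>-legend.tsv``.
    """
    style = style or CartoonStyle()
    cv = np.asarray(control_values, dtype=float)
    ev = np.asarray(experimental_values, dtype=float)
    rows, cols = cv.shape
    by_strain = {str(r["strain"]): r for _, r in stats.iterrows()}

    halo_color = {
        "excluded": style.excluded_cmp_halo,
        "dead_both": style.dead_both_halo,
        "significant": style.significant_halo,
    }
    halos = np.full(cv.shape, "", dtype=object)
    legend_rows = []
    seen = set()
    for r in range(rows):
        for c in range(cols):
            sid = str(position_strain[r, c])
            row = by_strain.get(sid)
            if row is None:
                continue        # missing stats: rendered unhighlighted
            state = _strain_state(row, p_threshold)
            if state:
                halos[r, c] = halo_color[state]
            if state and sid not in seen:
                seen.add(sid)
                legend_rows.append({
                    "strain": sid, "orf": row.get("orf", ""),
                    "position": f"{r + 1},{c + 1}", "state": state,
                    "p_value": row.get("p_value", np.nan),
                    "z_score": row.get("z_score", np.nan),
                    "growth_ratio": row.get("growth_ratio", np.nan),
                    "log_ratio": row.get("log_ratio", np.nan),
                })

    s = style.cell_px
    gutter = 2 * s
    w = 2 * cols * s + gutter
    h = rows * s + s
    parts = _svg_header(w, h, style)
    parts.append(f'<text x="4" y="{s - 6}" font-size="{s * 0.6:.0f}">control</text>')
    parts.append(
        f'<text x="{cols * s + gutter + 4}" y="{s - 6}" '
        f'font-size="{s * 0.6:.0f}">experimental</text>'
    )
    parts += _plate_elements(cv, halos, style, ox=0, oy=s)
    parts += _plate_elements(ev, halos, style, ox=cols * s + gutter, oy=s)
    parts.append("</svg>")
    svg = "\n".join(parts) + "\n"

    legend = pd.DataFrame(
        legend_rows,
        columns=["strain", "orf", "position", "state", "p_value", "z_score",
                 "growth_ratio", "log_ratio"],
    )
    if out_prefix is not None:
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        (prefix.parent / (prefix.name + ".svg")).write_text(svg)
        legend.to_csv(prefix.parent / (prefix.name + "-legend.tsv"), sep="\t",
                      index=False, float_format="%.6g", lineterminator="\n")
    return svg, legend


def export_selection(stats: pd.DataFrame, selection: list[str],
                     path: str | Path) -> Path:
    """Write the StrainStats rows of the selected strains to a TSV."""
    known = set(stats["strain"].astype(str))
    missing = [s for s in selection if s not in known]
    if missing:
        raise KeyError(f"unknown strain id(s): {missing}")
    sub = stats[stats["strain"].astype(str).isin(selection)]
    path = Path(path)
    sub.to_csv(path, sep="\t", index=False, float_format="%.6g",
               lineterminator="\n")
    return path


def svg_to_png(svg_values: np.ndarray, path: str | Path,
               low_growth: np.ndarray | None = None,
               excluded: np.ndarray | None = None,
               style: CartoonStyle | None = None) -> Path:
    """Rasterize a single-plate cartoon to PNG with matplotlib.

    Draws the same primitives as :func:`render_plate` (not an SVG parser).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle, Rectangle

    style = style or CartoonStyle()
    values = np.asarray(svg_values, dtype=float)
    rows, cols = values.shape
    halos = _halo_grid(values.shape, low_growth, excluded, style)
    s = style.cell_px
    fig, ax = plt.subplots(figsize=(cols * s / 72, rows * s / 72), dpi=72)
    ax.set_xlim(0, cols * s)
    ax.set_ylim(rows * s, 0)
    ax.axis("off")
    for r in range(rows):
        for c in range(cols):
            if halos[r, c]:
                ax.add_patch(Rectangle((c * s, r * s), s, s, color=halos[r, c]))
            rad = colony_radius(values[r, c], style)
            if rad > 0:
                ax.add_patch(Circle(((c + 0.5) * s, (r + 0.5) * s), rad,
                                    color=colony_color(values[r, c], style)))
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
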