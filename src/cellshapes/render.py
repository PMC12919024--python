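"""SVG illustrations of Fourier cell shapes.

A fitted body/nucleus coefficient pair renders as two closed smooth paths
(nucleus on top).  Truncating the series at a harmonic limit tunes coarseness:
limit 1 draws the best-fit ellipse, the full order reproduces every fitted
protrusion.  Output is deterministic SVG 1.1 text; the y-axis is flipped for
screen display (noted in the document header) and the micrometre-to-point
scale is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry2d import FourierShape, evaluate_fourier

__all__ = ["IllustrationStyle", "render_cell", "path_length"]


@dataclass
class IllustrationStyle:
    harmonic_limit: int = 15
    body_fill: str = "#d7e3f4"
    body_stroke: str = "#2b5797"
    nucleus_fill: str = "#b08bc9"
    nucleus_stroke: str = "#5e3370"
    stroke_width: float = 1.5  # pt
    scale: float = 4.0  # pt per um
    n_points: int = 256
    margin: float = 10.0  # pt

    def __post_init__(self) -> None:
        if self.harmonic_limit < 1:
            raise ValueError("harmonic_limit must be >= 1")
        if self.n_points < 16:
            raise ValueError("n_points must be >= 16")


def _sample(shape: FourierShape, limit: int, n_points: int) -> np.ndarray:
    truncated = shape.truncated(limit)
    theta = 2.0 * np.pi * np.arange(n_points) / n_points
    return evaluate_fourier(truncated, theta)


def path_length(points: np.ndarray) -> float:
    """Perimeter of a closed polyline (render-side length measure)."""
    d = np.diff(np.vstack([points, points[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _smooth_path(points: np.ndarray) -> str:
    """Closed smooth path through the sample points.

    Catmull-Rom spline converted to cubic Bezier segments, so the path stays
    smooth even at a coarse sample count; coordinates at fixed precision for
    byte-stable output.
    """
    p = points
    n = len(p)
    prev = np.roll(p, 1, axis=0)
    nxt = np.roll(p, -1, axis=0)
    nxt2 = np.roll(p, -2, axis=0)
    c1 = p + (nxt - prev) / 6.0
    c2 = nxt - (nxt2 - p) / 6.0

    def fmt(xy):
        return f"{xy[0]:.3f},{xy[1]:.3f}"

    parts = [f"M {fmt(p[0])}"]
    for i in range(n):
        parts.append(f"C {fmt(c1[i])} {fmt(c2[i])} {fmt(nxt[i])}")
    parts.append("Z")
    return " ".join(parts)


def _enclosed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return abs(0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def render_cell(
    f_body: FourierShape,
    f_nucleus: FourierShape,
    style: IllustrationStyle | None = None,
) -> str:
    """Render one cell as an SVG 1.1 document string."""
    style = style or IllustrationStyle()
    body = _sample(f_body, style.harmonic_limit, style.n_points)
    nucleus = _sample(f_nucleus, style.harmonic_limit, style.n_points)
    if _enclosed_area(nucleus) > _enclosed_area(body):
        warnings.warn("nucleus encloses more area than the body", stacklevel=2)

    pts = np.vstack([body, nucleus]) * style.scale
    pts[:, 1] *= -1.0  # flip y for screen coordinates
    lo = pts.min(axis=0) - style.margin
    hi = pts.max(axis=0) + style.margin
    size = hi - lo

    def to_screen(um_points):
        s = um_points * style.scale
        s[:, 1] *= -1.0
        return s - lo

    body_path = _smooth_path(to_screen(body.copy()))
    nuc_path = _smooth_path(to_screen(nucleus.copy()))
    sw = f"{style.stroke_width:g}"
    return (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        "<!-- cellshapes illustration; y-axis flipped for screen display; "
        f"scale {style.scale:g} pt/um -->\n"
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{size[0]:.1f}" height="{size[1]:.1f}" '
        f'viewBox="0 0 {size[0]:.1f} {size[1]:.1f}">\n'
        f'  <path id="body" d="{body_path}" fill="{style.body_fill}" '
        f'stroke="{style.body_stroke}" stroke-width="{sw}"/>\n'
        f'  <path id="nucleus" d="{nuc_path}" fill="{style.nucleus_fill}" '
        f'stroke="{style.nucleus_stroke}" stroke-width="{sw}"/>\n'
        "</svg>\n"
    )
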