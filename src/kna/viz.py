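"""Rendering of localisation maps coloured by angle or group.

The SNPCA angle theta is mapped bijectively onto the hue circle,
``hue = ((theta + offset) mod 2*pi) / (2*pi)``, with saturation and value
held constant (encoding the radius as saturation proved visually
confusing and is available only behind a flag).  The offset rotates the
colour wheel; :func:`auto_hue_offset` picks it so that the angular mode
of the densest localisations lands on blue/violet, which makes tight
aggregates contrast with yellow/green background points.

Renders are deterministic rasters: identical inputs produce byte-identical
PNG files.
"""

from __future__ import annotations

from colorsys import hsv_to_rgb
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .io import LocalisationTable, Window

__all__ = [
    "RenderSpec",
    "theta_to_hue",
    "auto_hue_offset",
    "hue_to_rgb",
    "group_colours",
    "render_points",
]

TWO_PI = 2.0 * np.pi

#: Hue placed on the angular mode of the densest localisations by
#: :func:`auto_hue_offset` (0.75 = blue/violet).
DENSE_TARGET_HUE = 0.75

# colour key for up to nine groups, matched to common SMLM colour naming
GROUP_COLOUR_NAMES = [
    "red", "blue", "cyan", "magenta", "green", "purple",
    "coral", "violet", "black",
]
_NAMED_RGB = {
    "red": (230, 25, 28),
    "blue": (31, 80, 225),
    "cyan": (40, 200, 220),
    "magenta": (220, 40, 200),
    "green": (60, 180, 75),
    "purple": (130, 60, 180),
    "coral": (250, 140, 110),
    "violet": (170, 120, 250),
    "black": (20, 20, 20),
}


def theta_to_hue(theta: np.ndarray, offset: float = 0.0) -> np.ndarray:
    """Map angles in (-pi, pi] onto hues in [0, 1).

    Periodic (theta and theta + 2*pi agree) and bijective on one period;
    angles pi apart give complementary hues 0.5 apart.
    """
    theta = np.asarray(theta, float)
    return np.mod(theta + offset, TWO_PI) / TWO_PI


def auto_hue_offset(
    theta: np.ndarray,
    density: np.ndarray,
    dense_fraction: float = 0.1,
    target_hue: float = DENSE_TARGET_HUE,
) -> float:
    """Offset placing the dense-localisation angular mode at ``target_hue``.

    The circular mean angle of the top ``dense_fraction`` of localisations
    by density is computed and the offset chosen so it maps to
    ``target_hue`` (blue/violet by default); background points, which sit
    in a different angular region, then fall towards yellow/green.
    """
    theta = np.asarray(theta, float)
    density = np.asarray(density, float)
    ok = np.isfinite(theta) & np.isfinite(density)
    theta, density = theta[ok], density[ok]
    cutoff = np.quantile(density, 1 - dense_fraction)
    dense = theta[density >= cutoff]
    mode = float(np.arctan2(np.sin(dense).mean(), np.cos(dense).mean()))
    return float(np.mod(target_hue * TWO_PI - mode, TWO_PI))


def hue_to_rgb(
    hue: np.ndarray, saturation: np.ndarray | float = 0.9, value: float = 0.95
) -> np.ndarray:
    """(N, 3) uint8 colours at constant saturation/value."""
    hue = np.atleast_1d(np.asarray(hue, float))
    sat = np.broadcast_to(np.asarray(saturation, float), hue.shape)
    out = np.empty((hue.size, 3), dtype=np.uint8)
    for i, (h, s) in enumerate(zip(hue.ravel(), sat.ravel())):
        out[i] = [round(c * 255) for c in hsv_to_rgb(h, s, value)]
    return out


def group_colours(labels: np.ndarray, colour_key: dict[int, str] | None = None) -> np.ndarray:
    """Per-localisation RGB colours from group labels.

    ``colour_key`` maps group label to a colour name from the built-in
    palette; by default groups 1..9 take the palette in order.  Label 0
    (invalid localisations) renders grey.
    """
    labels = np.asarray(labels, int)
    out = np.full((labels.size, 3), 128, dtype=np.uint8)
    present = sorted(set(labels.tolist()) - {0})
    if colour_key is None:
        if len(present) <= len(GROUP_COLOUR_NAMES):
            colour_key = {g: GROUP_COLOUR_NAMES[i] for i, g in enumerate(present)}
        else:
            # more groups than named colours: evenly spaced hues
            hues = np.linspace(0.0, 1.0, len(present), endpoint=False)
            rgb = hue_to_rgb(hues)
            for g, c in zip(present, rgb):
                out[labels == g] = c
            return out
    for g in present:
        if g not in colour_key:
            raise KeyError(f"no colour for group {g}")
        name = colour_key[g]
        if name not in _NAMED_RGB:
            raise KeyError(f"unknown colour name {name!r} for group {g}")
        out[labels == g] = _NAMED_RGB[name]
    return out


@dataclass(frozen=True)
class RenderSpec:
    """Raster parameters for :func:`render_points`."""

    width: int = 800
    height: int = 800
    point_radius: float = 1.0
    background: tuple[int, int, int] = (0, 0, 0)
    colour_key: dict = field(default_factory=dict)


def render_points(
    table: LocalisationTable,
    colours: np.ndarray,
    path: str | Path,
    spec: RenderSpec = RenderSpec(),
    window: Window | None = None,
) -> Path:
    """Scatter-render localisations to a PNG file.

    Coordinates are mapped affinely into the raster preserving aspect
    ratio and orientation (y increases upwards).  One RGB colour per
    localisation is required.  Output bytes are a pure function of the
    inputs.
    """
    colours = np.asarray(colours)
    if colours.shape != (len(table), 3):
        raise ValueError(
            f"need one RGB colour per localisation: got {colours.shape}, "
            f"expected ({len(table)}, 3)"
        )
    if window is None:
        if len(table) == 0:
            raise ValueError("cannot infer a window from an empty table")
        window = Window(
            float(table.x.min()), float(max(table.x.max(), table.x.min() + 1e-9)),
            float(table.y.min()), float(max(table.y.max(), table.y.min() + 1e-9)),
        )
    scale = min(
        spec.width / (window.xmax - window.xmin),
        spec.height / (window.ymax - window.ymin),
    )
    px = (table.x - window.xmin) * scale
    py = spec.height - (table.y - window.ymin) * scale  # y up

    img = Image.new("RGB", (spec.width, spec.height), spec.background)
    draw = ImageDraw.Draw(img)
    r = spec.point_radius
    for cx, cy, rgb in zip(px, py, colours):
        draw.ellipse(
            [cx - r, cy - r, cx + r, cy + r], fill=tuple(int(c) for c in rgb)
        )
    path = Path(path)
    img.save(path, format="PNG")
    return path
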