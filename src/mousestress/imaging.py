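"""Temporally color-mapped trajectory images of raw pointer events.

A session is rendered as a scatter of its original (non-interpolated)
events on a white canvas whose axes map the participant's screen.  Move
events are colored along a fixed perceptually ordered purple→yellow
gradient by their relative position in the sequence — the first point is
always the gradient's purple endpoint, the last always its yellow
endpoint.  Click events are black and drawn last, on top.  A baseline
image can be stacked under the application image for designs that keep
the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image, ImageDraw

from .cohort import EventKind, TaskSession

__all__ = ["CanvasConfig", "TrajectoryImage", "render_trajectory", "stack_baseline"]

# Gradient endpoints of the pinned purple→yellow colormap (viridis).
GRADIENT_FIRST_RGB = (68, 1, 84)
GRADIENT_LAST_RGB = (253, 231, 37)
CLICK_RGB = (0, 0, 0)
BACKGROUND_RGB = (255, 255, 255)


@dataclass(frozen=True)
class CanvasConfig:
    """Rendering configuration: canvas size, dot radius, colormap name."""

    width: int = 224
    height: int = 224
    dot_radius: int = 2
    colormap: str = "viridis"


@dataclass
class TrajectoryImage:
    """RGB raster of one rendered session."""

    raster: np.ndarray  # H×W×3 uint8
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=np.uint8)
        if self.raster.ndim != 3 or self.raster.shape[2] != 3:
            raise ValueError("raster must be H×W×3")

    @property
    def width(self) -> int:
        return self.raster.shape[1]

    @property
    def height(self) -> int:
        return self.raster.shape[0]

    def to_pil(self) -> Image.Image:
        return Image.fromarray(self.raster, mode="RGB")

    def save(self, path: str | Path) -> None:
        self.to_pil().save(Path(path), format="PNG")


def _gradient_colors(n: int, colormap: str) -> list[tuple[int, int, int]]:
    """n colors at relative positions i/(n−1); endpoints are fixed."""
    cmap = colormaps[colormap]
    if n == 1:
        pos = np.array([0.0])
    else:
        pos = np.arange(n) / (n - 1)
    rgba = cmap(pos)
    return [tuple(int(round(c * 255)) for c in row[:3]) for row in rgba]


def render_trajectory(
    s: TaskSession, canvas: CanvasConfig = CanvasConfig()
) -> TrajectoryImage:
    """Render a session's raw events as a color-mapped scatter image."""
    if not s.events:
        raise ValueError("cannot render a session with zero events")
    img = Image.new("RGB", (canvas.width, canvas.height), BACKGROUND_RGB)
    draw = ImageDraw.Draw(img)

    def to_canvas(x: float, y: float) -> tuple[float, float]:
        cx = x / s.screen_w * (canvas.width - 1)
        cy = y / s.screen_h * (canvas.height - 1)
        return cx, cy

    def dot(x: float, y: float, rgb: tuple[int, int, int]) -> None:
        r = canvas.dot_radius
        draw.ellipse([x - r, y - r, x + r, y + r], fill=rgb)

    moves = [e for e in s.events if e.kind is EventKind.MOVE]
    colors = _gradient_colors(len(moves), canvas.colormap)
    for e, rgb in zip(moves, colors):
        dot(*to_canvas(e.x, e.y), rgb)
    # clicks go on top
    for e in s.events:
        if e.kind is not EventKind.MOVE:
            dot(*to_canvas(e.x, e.y), CLICK_RGB)

    return TrajectoryImage(
        raster=np.asarray(img),
        meta={"session": tuple(str(k) for k in s.key), "canvas": canvas},
    )


def stack_baseline(app: TrajectoryImage, base: TrajectoryImage) -> TrajectoryImage:
    """Stack the application image on top of the baseline image."""
    if app.width != base.width:
        raise ValueError(
            f"width mismatch: application {app.width} vs baseline {base.width}"
        )
    raster = np.vstack([app.raster, base.raster])
    return TrajectoryImage(raster=raster, meta={"stacked": (app.meta, base.meta)})
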