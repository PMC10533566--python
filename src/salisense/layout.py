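"""Sensor geometry: where the 12 circular spots sit on the scanned image.

Coordinates are image-style: origin at the top-left pixel, x rightward,
y downward, 0-based.  A pixel belongs to a spot when its integer centre lies
within the disk (distance <= radius); there is no anti-aliased partial
coverage, so every mask is exactly enumerable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Tuple

import numpy as np
import yaml

from .config import LayoutConfig


class LayoutError(ValueError):
    """Raised for geometrically invalid spot layouts."""


@dataclass(frozen=True)
class SensorLayout:
    """Canvas size plus 12 (center_x, center_y, radius) disks, S1 -> S12."""

    canvas_width: int
    canvas_height: int
    spots: Tuple[Tuple[float, float, float], ...]

    def __post_init__(self):
        if len(self.spots) != 12:
            raise LayoutError(f"layout must define 12 spots, got {len(self.spots)}")
        for cx, cy, r in self.spots:
            if r <= 0:
                raise LayoutError("spot radius must be positive")
            if cx - r < 0 or cx + r >= self.canvas_width \
                    or cy - r < 0 or cy + r >= self.canvas_height:
                raise LayoutError(f"spot ({cx}, {cy}, r={r}) exceeds the canvas")
        for i in range(12):
            for j in range(i + 1, 12):
                xi, yi, ri = self.spots[i]
                xj, yj, rj = self.spots[j]
                if (xi - xj) ** 2 + (yi - yj) ** 2 <= (ri + rj) ** 2:
                    raise LayoutError(f"spots S{i + 1} and S{j + 1} overlap")

    @property
    def shape(self) -> Tuple[int, int]:
        """(height, width) of the expected image array."""
        return (self.canvas_height, self.canvas_width)

    def spot_mask(self, index: int) -> np.ndarray:
        """Boolean (H, W) mask of spot ``index`` (0-based)."""
        cx, cy, r = self.spots[index]
        yy, xx = np.ogrid[0:self.canvas_height, 0:self.canvas_width]
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2

    def masks(self) -> List[np.ndarray]:
        return [self.spot_mask(i) for i in range(12)]

    def to_dict(self) -> dict:
        return {
            "canvas_width": self.canvas_width,
            "canvas_height": self.canvas_height,
            "spots": [list(s) for s in self.spots],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SensorLayout":
        return cls(int(data["canvas_width"]), int(data["canvas_height"]),
                   tuple(tuple(float(v) for v in s) for s in data["spots"]))

    def save(self, path) -> None:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            if path.suffix in (".yml", ".yaml"):
                yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
            else:
                json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "SensorLayout":
        path = Path(path)
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        return cls.from_dict(data)


def grid_layout(config: LayoutConfig | None = None) -> SensorLayout:
    """Regular rows x cols grid of spots, S1..S12 in row-major order."""
    config = config or LayoutConfig()
    w, h = config.canvas_width, config.canvas_height
    spots = []
    for row in range(config.rows):
        for col in range(config.cols):
            cx = (col + 0.5) * w / config.cols
            cy = (row + 0.5) * h / config.rows
            spots.append((cx, cy, float(config.radius)))
    return SensorLayout(w, h, tuple(spots))


DEFAULT_LAYOUT = grid_layout()
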