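"""Stroke template for the task glyph.

The assessment task is writing the six-stroke Chinese character 米 ("rice")
ten times. The template below stores the canonical stroke order — dot, short
left-falling, horizontal, vertical, left-falling, right-falling — as
polylines in the unit box (x right, y down), used both by the synthetic
session generator and by the task-score rubric's stroke-order matcher.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GlyphTemplate", "MI_TEMPLATE"]


@dataclass(frozen=True)
class GlyphTemplate:
    name: str
    strokes: tuple  # tuple of (n_i, 2) float arrays, coordinates in [0, 1]^2

    def __post_init__(self):
        for s in self.strokes:
            if s.ndim != 2 or s.shape[0] < 2 or s.shape[1] != 2:
                raise ValueError("each template stroke needs >= 2 (x, y) points")
            if s.min() < 0 or s.max() > 1:
                raise ValueError("template coordinates must lie in [0, 1]^2")

    @property
    def n_strokes(self) -> int:
        return len(self.strokes)

    def stroke_lengths(self) -> np.ndarray:
        return np.array([
            float(np.hypot(*np.diff(s, axis=0).T).sum()) for s in self.strokes
        ])


def _poly(*pts) -> np.ndarray:
    return np.asarray(pts, dtype=float)


#: 米 in standard stroke order.
MI_TEMPLATE = GlyphTemplate(
    name="mi",
    strokes=(
        _poly((0.32, 0.12), (0.40, 0.30)),            # dot
        _poly((0.68, 0.12), (0.60, 0.30)),            # short left-falling
        _poly((0.08, 0.48), (0.92, 0.48)),            # horizontal
        _poly((0.50, 0.08), (0.50, 0.95)),            # vertical
        _poly((0.46, 0.54), (0.28, 0.74), (0.10, 0.90)),  # left-falling
        _poly((0.54, 0.54), (0.72, 0.74), (0.90, 0.90)),  # right-falling
    ),
)
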