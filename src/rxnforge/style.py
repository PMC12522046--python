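"""Rendering style: augmentation ranges and their per-image realizations.

Augmentation covers font size, arrow/bond line width, molecule depiction
scale, and the layout pattern (single-line, multiple-line, branch, cycle).
Fonts come from matplotlib's packaged DejaVu family — two faces shipped with
the pinned environment — so rendering never depends on system fonts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import matplotlib

from .rng import RNGStream
from .scheme import PATTERNS

_FONT_DIR = os.path.join(os.path.dirname(matplotlib.__file__), "mpl-data", "fonts", "ttf")
BUNDLED_FONTS = (
    os.path.join(_FONT_DIR, "DejaVuSans.ttf"),
    os.path.join(_FONT_DIR, "DejaVuSerif.ttf"),
)


@dataclass
class StyleConfig:
    font_size_range: tuple[int, int] = (11, 18)
    line_width_range: tuple[int, int] = (1, 3)
    molecule_scale_range: tuple[float, float] = (0.8, 1.3)
    pattern_weights: dict[str, float] = field(
        default_factory=lambda: {p: 0.25 for p in PATTERNS}
    )
    canvas_max_width: int = 1400
    seed: int = 0
    # optional tilted condition text, off by default; angle drawn in degrees
    rotation_range: tuple[float, float] = (-30.0, 30.0)
    p_rotate: float = 0.0
    fonts: tuple[str, str] = BUNDLED_FONTS

    def validate(self) -> None:
        for name, (lo, hi) in (
            ("font_size_range", self.font_size_range),
            ("line_width_range", self.line_width_range),
            ("molecule_scale_range", self.molecule_scale_range),
        ):
            if lo > hi:
                raise ValueError(f"{name}: min {lo} > max {hi}")
        total = sum(self.pattern_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pattern_weights sum to {total}, expected 1")
        for p in self.pattern_weights:
            if p not in PATTERNS:
                raise ValueError(f"unknown pattern {p!r}")
        if self.canvas_max_width < 200:
            raise ValueError("canvas_max_width too small to place any molecule")


@dataclass(frozen=True)
class StyleDraw:
    """One concrete realization of the augmentation axes."""

    font_size: int
    line_width: int
    molecule_scale: float
    pattern: str
    font_path: str
    rotation: Optional[float] = None  # degrees; None = horizontal text


def draw_style(style: StyleConfig, rng: RNGStream) -> StyleDraw:
    """Sample one style draw: uniform within each range, pattern by weight."""
    style.validate()
    g = rng.generator()
    fs_lo, fs_hi = style.font_size_range
    lw_lo, lw_hi = style.line_width_range
    sc_lo, sc_hi = style.molecule_scale_range
    patterns = sorted(style.pattern_weights)
    weights = [style.pattern_weights[p] for p in patterns]
    pattern = patterns[int(g.choice(len(patterns), p=weights))]
    rotation = None
    if style.p_rotate > 0 and g.random() < style.p_rotate:
        rotation = float(g.uniform(style.rotation_range[0], style.rotation_range[1]))
    return StyleDraw(
        font_size=int(g.integers(fs_lo, fs_hi + 1)),
        line_width=int(g.integers(lw_lo, lw_hi + 1)),
        molecule_scale=float(g.uniform(sc_lo, sc_hi)) if sc_hi > sc_lo else float(sc_lo),
        pattern=pattern,
        font_path=style.fonts[int(g.integers(len(style.fonts)))],
        rotation=rotation,
    )
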