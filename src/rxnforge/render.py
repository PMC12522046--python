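"""Rasterize a laid-out reaction scheme to an 8-bit RGB PNG.

After drawing, every component and condition-item box is re-measured: the
final annotation box is the tight box of the actually drawn glyphs inside
the allocated layout box.  Tightening only ever shrinks boxes, so layout
guarantees (molecule non-overlap, containment in canvas) survive.
Rendering is deterministic given the scheme, the style draw and the bundled
fonts.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Optional

import numpy as np
from PIL import Image, ImageDraw

from .depict import RDKitDepictor
from .layout import load_font, text_extent
from .scheme import Arrow, BBox, Component, ReactionScheme
from .style import StyleDraw

_WHITE_THRESHOLD = 250  # pixel considered background if all channels above


def _draw_text_box(canvas: Image.Image, text: str, box: BBox, font, rotation: Optional[float]) -> None:
    if rotation:
        w, h = text_extent(text, font)
        tile = Image.new("RGBA", (w + 4, h + 4), (255, 255, 255, 0))
        td = ImageDraw.Draw(tile)
        x0, y0, _, _ = font.getbbox(text)
        td.text((2 - x0, 2 - y0), text, font=font, fill=(0, 0, 0, 255))
        tile = tile.rotate(rotation, expand=True, resample=Image.BICUBIC)
        px = int(round(box.center[0] - tile.width / 2.0))
        py = int(round(box.center[1] - tile.height / 2.0))
        canvas.paste(tile, (px, py), tile)
    else:
        d = ImageDraw.Draw(canvas)
        x0, y0, _, _ = font.getbbox(text)
        d.text((box.x_min - x0, box.y_min - y0), text, font=font, fill=(0, 0, 0))


def _arrowhead(d: ImageDraw.ImageDraw, tip, direction, size: float, width: int) -> None:
    dx, dy = direction
    norm = math.hypot(dx, dy) or 1.0
    ux, uy = dx / norm, dy / norm
    px, py = -uy, ux
    base = (tip[0] - ux * size, tip[1] - uy * size)
    left = (base[0] + px * size * 0.45, base[1] + py * size * 0.45)
    right = (base[0] - px * size * 0.45, base[1] - py * size * 0.45)
    d.polygon([tip, left, right], fill=(0, 0, 0))


def _arc_points(arrow: Arrow, n: int = 24) -> list[tuple[float, float]]:
    """Quadratic-Bezier-like path through start, control point(s), end."""
    pts = [arrow.start, *arrow.control_points, arrow.end]
    if len(pts) == 2:
        return list(pts)
    # de Casteljau over however many control points exist
    out = []
    for t in (i / (n - 1) for i in range(n)):
        layer = list(pts)
        while len(layer) > 1:
            layer = [
                (
                    (1 - t) * layer[i][0] + t * layer[i + 1][0],
                    (1 - t) * layer[i][1] + t * layer[i + 1][1],
                )
                for i in range(len(layer) - 1)
            ]
        out.append(layer[0])
    return out


def _draw_arrow(d: ImageDraw.ImageDraw, arrow: Arrow, width: int) -> None:
    head = max(9.0, 4.0 * width)
    if arrow.kind == "curved":
        path = _arc_points(arrow)
        d.line(path, fill=(0, 0, 0), width=width, joint="curve")
        _arrowhead(d, path[-1], (path[-1][0] - path[-2][0], path[-1][1] - path[-2][1]), head, width)
    else:
        d.line([arrow.start, arrow.end], fill=(0, 0, 0), width=width)
        direction = (arrow.end[0] - arrow.start[0], arrow.end[1] - arrow.start[1])
        _arrowhead(d, arrow.end, direction, head, width)
        if arrow.kind == "bidirectional":
            _arrowhead(d, arrow.start, (-direction[0], -direction[1]), head, width)
    if arrow.crossed_out:
        mx, my = arrow.midpoint
        r = head * 0.9
        d.line([(mx - r, my - r), (mx + r, my + r)], fill=(0, 0, 0), width=width + 1)
        d.line([(mx - r, my + r), (mx + r, my - r)], fill=(0, 0, 0), width=width + 1)


def _tighten(arr: np.ndarray, box: BBox, canvas_w: int, canvas_h: int) -> BBox:
    """Tight box of non-background pixels inside ``box``; falls back to ``box``."""
    x0 = max(0, int(math.floor(box.x_min)))
    y0 = max(0, int(math.floor(box.y_min)))
    x1 = min(canvas_w, int(math.ceil(box.x_max)))
    y1 = min(canvas_h, int(math.ceil(box.y_max)))
    if x1 <= x0 or y1 <= y0:
        return box
    crop = arr[y0:y1, x0:x1]
    mask = (crop < _WHITE_THRESHOLD).any(axis=2)
    if not mask.any():
        return box
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return BBox(
        x0 + int(cols[0]), y0 + int(rows[0]), x0 + int(cols[-1]) + 1, y0 + int(rows[-1]) + 1
    )


def render_scheme(
    scheme: ReactionScheme,
    draw: StyleDraw,
    depictor: Optional[RDKitDepictor] = None,
) -> tuple[Image.Image, ReactionScheme]:
    """Draw the scheme; return the image and the scheme with tightened boxes."""
    depictor = depictor or RDKitDepictor()
    font = load_font(draw.font_path, draw.font_size)
    w, h = int(math.ceil(scheme.canvas_width)), int(math.ceil(scheme.canvas_height))
    canvas = Image.new("RGB", (w, h), (255, 255, 255))
    d = ImageDraw.Draw(canvas)

    for comp in scheme.components:
        if comp.is_molecule:
            tile = depictor.draw(
                comp.smiles,
                max(1, int(round(comp.bbox.width))),
                max(1, int(round(comp.bbox.height))),
                draw.line_width,
            )
            canvas.paste(tile, (int(round(comp.bbox.x_min)), int(round(comp.bbox.y_min))))
        else:
            for item in comp.items or []:
                _draw_text_box(canvas, item.text, item.bbox, font, draw.rotation)
    for text, box in scheme.decorations:
        _draw_text_box(canvas, text, box, font, None)
    for step in scheme.steps:
        _draw_arrow(d, step.arrow, draw.line_width)

    # re-measure: tight boxes of the drawn glyphs
    arr = np.asarray(canvas)
    final_components: list[Component] = []
    for comp in scheme.components:
        if comp.is_molecule:
            tight = _tighten(arr, comp.bbox, w, h)
            final_components.append(replace_component(comp, tight, None))
        else:
            items = [replace(i, bbox=_tighten(arr, i.bbox, w, h)) for i in (comp.items or [])]
            bbox = BBox.union([i.bbox for i in items]) if items else comp.bbox
            final_components.append(replace_component(comp, bbox, items))
    final = ReactionScheme(
        canvas_width=w,
        canvas_height=h,
        components=final_components,
        steps=scheme.steps,
        pattern=scheme.pattern,
        decorations=scheme.decorations,
    )
    return canvas, final


def replace_component(comp: Component, bbox: BBox, items) -> Component:
    return Component(comp.id, comp.role, bbox, smiles=comp.smiles,
                     items=items if not comp.is_molecule else None)
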