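"""Scheme layout: place molecules, arrows and condition text for the four
reaction-image patterns.

Placement follows the conventions of printed reaction schemes: reactants,
arrow, products run left to right with "+" between co-reactants; agent text
sits above the arrow and solvent/temperature/time/yield (and auxiliary
"other" text) stack below it.  Layout works entirely in box space — nothing
is rasterized here — and its output always satisfies ``validate_scheme``.

Patterns:

* ``single_line`` — one reaction line, wrapping to a continuation line when
  the content exceeds ``canvas_max_width``; chained steps continue from the
  previous product.
* ``multiple_line`` — one step per row.
* ``branch`` — one shared reactant set with several outgoing arrows, one
  product row per arm.
* ``cycle`` — single-molecule nodes on a closed circle joined by curved
  arrows (requires at least 3 steps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

from PIL import ImageFont

from .conditions import ConditionItem
from .depict import RDKitDepictor
from .reactions import ReactionInput
from .scheme import Arrow, BBox, Component, ReactionScheme, ReactionStep
from .style import StyleConfig, StyleDraw

MARGIN = 22          # outer canvas margin, px
H_SPACING = 16       # gap between elements in a row
LINE_GAP = 34        # vertical gap between reaction lines
ARROW_GAP = 7        # gap between the arrow line and condition text
MIN_ARROW = 80       # minimum arrow length, px


class LayoutError(RuntimeError):
    """Unsatisfiable layout, e.g. a molecule wider than the canvas at minimum scale."""


@dataclass
class LayoutStep:
    """One reaction step to lay out: source reaction + its condition items."""

    reaction: ReactionInput
    conditions: list[ConditionItem]
    arrow_kind: str = "straight"
    crossed_out: bool = False


# --------------------------------------------------------------------------
# text metrics

_FONT_CACHE: dict[tuple[str, int], ImageFont.FreeTypeFont] = {}


def load_font(path: str, size: int) -> ImageFont.FreeTypeFont:
    key = (path, int(size))
    if key not in _FONT_CACHE:
        _FONT_CACHE[key] = ImageFont.truetype(path, int(size))
    return _FONT_CACHE[key]


def text_extent(text: str, font: ImageFont.FreeTypeFont) -> tuple[int, int]:
    x0, y0, x1, y1 = font.getbbox(text)
    return (max(1, x1 - x0), max(1, y1 - y0))


def _rotated_extent(w: int, h: int, angle_deg: Optional[float]) -> tuple[int, int]:
    if not angle_deg:
        return (w, h)
    a = math.radians(angle_deg)
    return (
        int(math.ceil(abs(w * math.cos(a)) + abs(h * math.sin(a)))),
        int(math.ceil(abs(w * math.sin(a)) + abs(h * math.cos(a)))),
    )


# --------------------------------------------------------------------------
# arrow block: an arrow plus its surrounding condition text

_BELOW_ORDER = {"solvent": 0, "temperature": 1, "time": 2, "yield": 3, "other": 4}


@dataclass
class _ArrowBlock:
    step: LayoutStep
    arrow_len: float
    above: list[tuple[ConditionItem, int, int]]   # item, w, h
    above_w: int
    above_h: int
    below: list[tuple[ConditionItem, int, int]]
    below_w: int
    below_h: int

    @property
    def ascent(self) -> float:
        return self.above_h + (ARROW_GAP if self.above else 0) + 4

    @property
    def descent(self) -> float:
        return self.below_h + (ARROW_GAP if self.below else 0) + 4

    def realize(self, x: float, cy: float) -> tuple[Arrow, list[ConditionItem], list[tuple[str, BBox]]]:
        """Place arrow and items with the arrow line on y = cy starting at x."""
        arrow = Arrow(
            start=(x, cy),
            end=(x + self.arrow_len, cy),
            kind=self.step.arrow_kind,
            crossed_out=self.step.crossed_out,
        )
        items, decos = self._place_items((x + self.arrow_len / 2.0, cy))
        return arrow, items, decos

    def _place_items(self, mid: tuple[float, float]) -> tuple[list[ConditionItem], list[tuple[str, BBox]]]:
        midx, midy = mid
        placed: list[ConditionItem] = []
        decos: list[tuple[str, BBox]] = []
        if self.above:
            cx = midx - self.above_w / 2.0
            y1 = midy - ARROW_GAP
            for idx, (item, w, h) in enumerate(self.above):
                box = BBox(cx, y1 - self.above_h, cx + w, y1 - self.above_h + h).round()
                placed.append(replace(item, bbox=box))
                cx += w
                if idx < len(self.above) - 1:
                    decos.append((",", BBox(cx, y1 - self.above_h, cx + 6, y1).round()))
                    cx += 12
        y = midy + ARROW_GAP
        for item, w, h in self.below:
            box = BBox(midx - w / 2.0, y, midx - w / 2.0 + w, y + h).round()
            placed.append(replace(item, bbox=box))
            y += h + 4
        return placed, decos


def _build_arrow_block(
    step: LayoutStep, font: ImageFont.FreeTypeFont, rotation: Optional[float]
) -> _ArrowBlock:
    above: list[tuple[ConditionItem, int, int]] = []
    below: list[tuple[ConditionItem, int, int]] = []
    for item in step.conditions:
        w, h = _rotated_extent(*text_extent(item.text, font), rotation)
        if item.role == "agent":
            above.append((item, w, h))
        else:
            below.append((item, w, h))
    below.sort(key=lambda t: _BELOW_ORDER.get(t[0].role, 9))
    above_w = sum(w for _, w, _ in above) + 12 * max(0, len(above) - 1)
    above_h = max((h for _, _, h in above), default=0)
    below_w = max((w for _, w, _ in below), default=0)
    below_h = sum(h for _, _, h in below) + 4 * max(0, len(below) - 1)
    arrow_len = max(MIN_ARROW, above_w + 18, below_w + 18)
    return _ArrowBlock(step, arrow_len, above, above_w, above_h, below, below_w, below_h)


# --------------------------------------------------------------------------
# scheme assembly helper


class _Builder:
    def __init__(self, pattern: str):
        self.pattern = pattern
        self.components: list[Component] = []
        self.steps: list[ReactionStep] = []
        self.decorations: list[tuple[str, BBox]] = []
        self._mol_index: dict[tuple[int, str], str] = {}  # (node_key, smiles) -> id

    def new_id(self) -> str:
        return f"comp{len(self.components)}"

    def add_molecule(self, smiles: str, role: str, bbox: BBox) -> str:
        cid = self.new_id()
        self.components.append(Component(cid, role, bbox.round(), smiles=smiles))
        return cid

    def add_condition(self, items: list[ConditionItem]) -> Optional[str]:
        if not items:
            return None
        cid = self.new_id()
        bbox = BBox.union([i.bbox for i in items]).round()
        self.components.append(Component(cid, "condition", bbox, items=list(items)))
        return cid

    def add_step(self, r_ids, c_id, p_ids, arrow: Arrow) -> None:
        self.steps.append(
            ReactionStep(list(r_ids), [c_id] if c_id else [], list(p_ids), arrow)
        )

    def finish(self) -> ReactionScheme:
        boxes = [c.bbox for c in self.components] + [b for _, b in self.decorations]
        xs = [b.x_min for b in boxes] + [b.x_max for b in boxes]
        ys = [b.y_min for b in boxes] + [b.y_max for b in boxes]
        for s in self.steps:
            pts = [s.arrow.start, s.arrow.end, *s.arrow.control_points]
            xs.extend(p[0] for p in pts)
            ys.extend(p[1] for p in pts)
        dx, dy = MARGIN - min(xs), MARGIN - min(ys)
        w = int(math.ceil(max(xs) - min(xs))) + 2 * MARGIN
        h = int(math.ceil(max(ys) - min(ys))) + 2 * MARGIN

        def shift_box(b: BBox) -> BBox:
            return b.translate(dx, dy).round()

        for c in self.components:
            c.bbox = shift_box(c.bbox)
            if c.items is not None:
                c.items = [replace(i, bbox=shift_box(i.bbox)) for i in c.items]
        self.decorations = [(t, shift_box(b)) for t, b in self.decorations]
        for s in self.steps:
            s.arrow = Arrow(
                (s.arrow.start[0] + dx, s.arrow.start[1] + dy),
                (s.arrow.end[0] + dx, s.arrow.end[1] + dy),
                s.arrow.kind,
                s.arrow.crossed_out,
                tuple((p[0] + dx, p[1] + dy) for p in s.arrow.control_points),
            )
        return ReactionScheme(w, h, self.components, self.steps, self.pattern, self.decorations)


# --------------------------------------------------------------------------
# row layout (single_line, multiple_line)


@dataclass
class _Element:
    kind: str                      # "mol" | "plus" | "arrow"
    width: float
    ascent: float
    descent: float
    smiles: Optional[str] = None
    role: Optional[str] = None
    block: Optional[_ArrowBlock] = None


def _step_elements(
    step: LayoutStep,
    font: ImageFont.FreeTypeFont,
    depictor: RDKitDepictor,
    scale: float,
    rotation: Optional[float],
    include_reactants: bool = True,
) -> list[_Element]:
    plus_w, plus_h = text_extent("+", font)
    out: list[_Element] = []

    def mols(smiles_list, role):
        for j, smi in enumerate(smiles_list):
            if j > 0:
                out.append(_Element("plus", plus_w, plus_h / 2, plus_h / 2))
            w, h = depictor.size(smi, scale)
            out.append(_Element("mol", w, h / 2, h / 2, smiles=smi, role=role))

    if include_reactants:
        mols(step.reaction.reactants, "reactant")
    block = _build_arrow_block(step, font, rotation)
    out.append(_Element("arrow", block.arrow_len, block.ascent, block.descent, block=block))
    mols(step.reaction.products, "product")
    return out


@dataclass
class _StepPart:
    arrow: Arrow
    cond_id: Optional[str]
    r_ids: list[str]
    p_ids: list[str]


def _layout_rows(
    builder: _Builder,
    rows: list[list[_Element]],
    max_width: float,
    wrap: bool = True,
) -> float:
    """Place rows of elements; each row may wrap into continuation lines.

    Within one row, molecules between two arrows are the products of the
    earlier arrow and the reactants of the later one (a chained line like
    ``A -> B -> C``).  Returns the y coordinate below the content.
    """
    y = 0.0
    for elements in rows:
        for e in elements:
            if e.width + 2 * MARGIN > max_width:
                raise LayoutError(
                    f"element of width {e.width:.0f}px cannot fit canvas_max_width {max_width}"
                )
        # greedy wrap into lines
        lines: list[list[_Element]] = [[]]
        x = 0.0
        for e in elements:
            w = e.width + (H_SPACING if lines[-1] else 0)
            if wrap and lines[-1] and x + w > max_width - 2 * MARGIN:
                lines.append([])
                x = 0.0
                w = e.width
            lines[-1].append(e)
            x += w

        parts: list[_StepPart] = []
        collected: list[str] = []  # molecule ids since the last arrow
        for line in lines:
            ascent = max(e.ascent for e in line)
            descent = max(e.descent for e in line)
            cy = y + ascent
            x = 0.0
            for e in line:
                if e.kind == "mol":
                    h = e.ascent + e.descent
                    box = BBox(x, cy - e.ascent, x + e.width, cy - e.ascent + h)
                    collected.append(builder.add_molecule(e.smiles, e.role, box))
                elif e.kind == "plus":
                    box = BBox(x, cy - e.ascent, x + e.width, cy + e.descent)
                    builder.decorations.append(("+", box.round()))
                elif e.kind == "arrow":
                    arrow, items, decos = e.block.realize(x, cy)
                    cond_id = builder.add_condition(items)
                    builder.decorations.extend(decos)
                    if parts:
                        parts[-1].p_ids = list(collected)
                    parts.append(_StepPart(arrow, cond_id, list(collected), []))
                    collected = []
                x += e.width + H_SPACING
            y += ascent + descent + LINE_GAP
        if parts:
            parts[-1].p_ids = list(collected)
        for p in parts:
            builder.add_step(p.r_ids, p.cond_id, p.p_ids, p.arrow)
    return y


# --------------------------------------------------------------------------
# pattern layouts


def _layout_single_line(builder, steps, font, depictor, draw, max_width):
    elements: list[_Element] = []
    prev_products: Optional[tuple[str, ...]] = None
    for i, step in enumerate(steps):
        chained = (
            i > 0
            and prev_products is not None
            and tuple(step.reaction.reactants) == prev_products
        )
        elements.extend(
            _step_elements(step, font, depictor, draw.molecule_scale, draw.rotation,
                           include_reactants=not chained)
        )
        prev_products = tuple(step.reaction.products)
    _layout_rows(builder, [elements], max_width)


def _layout_multiple_line(builder, steps, font, depictor, draw, max_width):
    rows = [
        _step_elements(s, font, depictor, draw.molecule_scale, draw.rotation)
        for s in steps
    ]
    _layout_rows(builder, rows, max_width)


def _layout_branch(builder, steps, font, depictor, draw, max_width):
    """Shared reactant set on the left, one arrow+product row per arm."""
    scale = draw.molecule_scale
    root = steps[0].reaction.reactants
    for s in steps[1:]:
        if tuple(s.reaction.reactants) != tuple(root):
            raise LayoutError("branch pattern requires all steps to share one reactant set")
    plus_w, plus_h = text_extent("+", font)

    # root column: molecules stacked vertically with "+" between
    root_sizes = [depictor.size(m, scale) for m in root]
    root_w = max(w for w, _ in root_sizes)
    plus_gap = plus_h + 16
    root_h = sum(h for _, h in root_sizes) + plus_gap * (len(root) - 1)

    # arm rows on the right
    arm_blocks = [_build_arrow_block(s, font, draw.rotation) for s in steps]
    arm_rows = []
    for s in steps:
        sizes = [depictor.size(m, scale) for m in s.reaction.products]
        w = sum(w for w, _ in sizes) + (plus_w + 2 * H_SPACING) * (len(sizes) - 1)
        h = max(h for _, h in sizes)
        arm_rows.append((sizes, w, h))
    arm_heights = [
        max(h, b.ascent + b.descent) for (_, _, h), b in zip(arm_rows, arm_blocks)
    ]
    arms_h = sum(arm_heights) + LINE_GAP * (len(steps) - 1)
    total_h = max(root_h, arms_h)

    # place root
    y_root = (total_h - root_h) / 2.0
    root_ids = []
    yc = y_root
    for j, ((w, h), smi) in enumerate(zip(root_sizes, root)):
        box = BBox((root_w - w) / 2.0, yc, (root_w - w) / 2.0 + w, yc + h)
        root_ids.append(builder.add_molecule(smi, "reactant", box))
        yc += h
        if j < len(root) - 1:
            by = yc + (plus_gap - plus_h) / 2.0
            builder.decorations.append(
                ("+", BBox(root_w / 2.0 - plus_w / 2.0, by, root_w / 2.0 + plus_w / 2.0, by + plus_h).round())
            )
            yc += plus_gap

    arrow_x0 = root_w + H_SPACING
    max_arrow = max(b.arrow_len for b in arm_blocks)
    prod_x0 = arrow_x0 + max_arrow + H_SPACING
    root_anchor = (root_w + 4, y_root + root_h / 2.0)

    y = (total_h - arms_h) / 2.0
    for (sizes, w, h), block, step, row_h in zip(arm_rows, arm_blocks, steps, arm_heights):
        cy = y + row_h / 2.0
        arrow = Arrow(
            start=root_anchor,
            end=(prod_x0 - H_SPACING + (max_arrow - block.arrow_len) / 2.0, cy),
            kind=step.arrow_kind,
            crossed_out=step.crossed_out,
        )
        items, decos = block._place_items(
            ((arrow.start[0] + arrow.end[0]) / 2.0, (arrow.start[1] + arrow.end[1]) / 2.0)
        )
        cond_id = builder.add_condition(items)
        builder.decorations.extend(decos)
        p_ids = []
        x = prod_x0
        for (w_i, h_i), smi in zip(sizes, step.reaction.products):
            if p_ids:
                builder.decorations.append(
                    ("+", BBox(x, cy - plus_h / 2.0, x + plus_w, cy + plus_h / 2.0).round())
                )
                x += plus_w + 2 * H_SPACING
            box = BBox(x, cy - h_i / 2.0, x + w_i, cy - h_i / 2.0 + h_i)
            p_ids.append(builder.add_molecule(smi, "product", box))
            x += w_i
        builder.add_step(root_ids, cond_id, p_ids, arrow)
        y += row_h + LINE_GAP


def _layout_cycle(builder, steps, font, depictor, draw, max_width):
    """Closed loop: node i -> node i+1 (mod k) with curved arc arrows."""
    k = len(steps)
    if k < 3:
        raise LayoutError("cycle pattern requires at least 3 steps")
    nodes: list[str] = []
    for i, s in enumerate(steps):
        if len(s.reaction.reactants) != 1 or len(s.reaction.products) != 1:
            raise LayoutError("cycle steps must be single-reactant, single-product")
        nodes.append(s.reaction.reactants[0])
        nxt = steps[(i + 1) % k].reaction.reactants[0]
        if s.reaction.products[0] != nxt:
            raise LayoutError("cycle steps must chain: product i == reactant i+1")

    scale = draw.molecule_scale
    sizes = [depictor.size(m, scale) for m in nodes]
    # radius so that adjacent boxes clear each other, then inflate until no overlap
    need = max(
        math.hypot(*sizes[i]) / 2.0 + math.hypot(*sizes[(i + 1) % k]) / 2.0 + 30
        for i in range(k)
    )
    radius = max(120.0, need / (2.0 * math.sin(math.pi / k)))
    angles = [-math.pi / 2.0 + 2.0 * math.pi * i / k for i in range(k)]

    for _ in range(30):
        boxes = []
        for (w, h), a in zip(sizes, angles):
            cx, cy = radius * math.cos(a), radius * math.sin(a)
            boxes.append(BBox(cx - w / 2.0, cy - h / 2.0, cx + w / 2.0, cy + h / 2.0))
        if all(
            boxes[i].intersection_area(boxes[j]) == 0.0
            for i in range(k)
            for j in range(i + 1, k)
        ):
            break
        radius *= 1.2
    else:
        raise LayoutError("cycle layout could not separate molecule boxes")

    node_ids = []
    for i, (smi, box) in enumerate(zip(nodes, boxes)):
        role = "reactant" if i == 0 else "product"  # role of first use
        node_ids.append(builder.add_molecule(smi, role, box))

    for i, step in enumerate(steps):
        a0, a1 = angles[i], angles[(i + 1) % k]
        if a1 <= a0:
            a1 += 2.0 * math.pi
        # trim the arc so it starts/ends at the node boundaries
        trim = min(0.48, 0.5 * (a1 - a0) - 0.08)
        b0, b1 = a0 + trim, a1 - trim
        start = (radius * math.cos(b0), radius * math.sin(b0))
        end = (radius * math.cos(b1), radius * math.sin(b1))
        bulge = radius * 1.16
        mids = [(b0 + b1) / 2.0]
        ctrl = tuple((bulge * math.cos(m), bulge * math.sin(m)) for m in mids)
        arrow = Arrow(start, end, "curved", step.crossed_out, ctrl)
        block = _build_arrow_block(step, font, draw.rotation)
        items, decos = block._place_items(arrow.midpoint)
        cond_id = builder.add_condition(items)
        builder.decorations.extend(decos)
        builder.add_step([node_ids[i]], cond_id, [node_ids[(i + 1) % k]], arrow)


# --------------------------------------------------------------------------
# entry point

_PATTERN_FUNCS = {
    "single_line": _layout_single_line,
    "multiple_line": _layout_multiple_line,
    "branch": _layout_branch,
    "cycle": _layout_cycle,
}


def layout_scheme(
    steps: list[LayoutStep],
    pattern: str,
    style: StyleConfig,
    draw: StyleDraw,
    depictor: Optional[RDKitDepictor] = None,
) -> ReactionScheme:
    """Place all boxes and arrows for ``steps`` under ``pattern``; no rasterization."""
    if not steps:
        raise LayoutError("need at least one step")
    if pattern not in _PATTERN_FUNCS:
        raise LayoutError(f"unknown pattern {pattern!r}")
    depictor = depictor or RDKitDepictor()
    font = load_font(draw.font_path, draw.font_size)
    builder = _Builder(pattern)
    _PATTERN_FUNCS[pattern](builder, steps, font, depictor, draw, style.canvas_max_width)
    return builder.finish()
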