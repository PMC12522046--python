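"""Token-sequence annotation codec.

Annotations are linearized into a flat token stream with *paired start–end
tokens* per reaction and per component, and *numeric coordinate tokens*: a
box is four integers obtained by quantizing each pixel coordinate onto a
grid of ``n_bins`` positions per axis (numeric coordinates localize more
precisely than a small learned location vocabulary, which is why this
format prefers them).

Layout of one reaction block::

    RXN_START
      RCT_START x0 y0 x1 y1 RCT_END        (one block per reactant)
      CND_START x0 y0 x1 y1 [Age] text ... CND_END
      PRD_START x0 y0 x1 y1 PRD_END
    RXN_END

Condition items appear inside the condition block as an optional role token
([Age]/[Sol]/[Tem]/[Time]/[Yld]) followed by one percent-escaped text token;
items with role "other" carry their text but *no* role token.  The decoder
is total: malformed streams yield a best-effort partial scheme plus
diagnostics, never an exception.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .scheme import (
    Arrow,
    BBox,
    Component,
    ConditionItem,
    ReactionScheme,
    ReactionStep,
)

RXN_START, RXN_END = "RXN_START", "RXN_END"
RCT_START, RCT_END = "RCT_START", "RCT_END"
CND_START, CND_END = "CND_START", "CND_END"
PRD_START, PRD_END = "PRD_START", "PRD_END"

STRUCTURAL_TOKENS = (
    RXN_START, RXN_END, RCT_START, RCT_END, CND_START, CND_END, PRD_START, PRD_END
)
ROLE_TOKENS = {
    "agent": "[Age]",
    "solvent": "[Sol]",
    "temperature": "[Tem]",
    "time": "[Time]",
    "yield": "[Yld]",
}
TOKEN_ROLES = {v: k for k, v in ROLE_TOKENS.items()}

DEFAULT_BINS = 1000


@dataclass(frozen=True)
class Vocabulary:
    n_bins: int = DEFAULT_BINS

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")

    def tokens(self) -> list[str]:
        return [*STRUCTURAL_TOKENS, *ROLE_TOKENS.values(),
                *(str(i) for i in range(self.n_bins))]


@dataclass
class TokenSequence:
    tokens: list[str]
    n_bins: int
    canvas_width: float
    canvas_height: float

    def to_text(self) -> str:
        return " ".join(self.tokens)

    @staticmethod
    def from_text(text: str, n_bins: int, canvas_width: float, canvas_height: float) -> "TokenSequence":
        return TokenSequence(text.split(), n_bins, canvas_width, canvas_height)


# --------------------------------------------------------------------------
# quantization


def quantize_coord(c: float, extent: float, n_bins: int) -> int:
    q = int(round(c / extent * (n_bins - 1)))
    return min(max(q, 0), n_bins - 1)


def dequantize_coord(q: int, extent: float, n_bins: int) -> float:
    return q / (n_bins - 1) * extent


def quantize_bbox(b: BBox, canvas: tuple[float, float], n_bins: int) -> tuple[int, int, int, int]:
    """Map a box inside ``canvas`` to 4 integer tokens in [0, n_bins-1]."""
    w, h = canvas
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if b.x_min < 0 or b.y_min < 0 or b.x_max > w + 1e-9 or b.y_max > h + 1e-9:
        raise ValueError(f"bbox {b} outside canvas {canvas}")
    return (
        quantize_coord(b.x_min, w, n_bins),
        quantize_coord(b.y_min, h, n_bins),
        quantize_coord(b.x_max, w, n_bins),
        quantize_coord(b.y_max, h, n_bins),
    )


def dequantize_bbox(q: Sequence[int], canvas: tuple[float, float], n_bins: int) -> BBox:
    w, h = canvas
    return BBox(
        dequantize_coord(q[0], w, n_bins),
        dequantize_coord(q[1], h, n_bins),
        dequantize_coord(q[2], w, n_bins),
        dequantize_coord(q[3], h, n_bins),
    )


# --------------------------------------------------------------------------
# encoding


_RESERVED = set(STRUCTURAL_TOKENS) | set(TOKEN_ROLES)


def _escape(text: str) -> str:
    esc = urllib.parse.quote(text, safe="")
    # a text token must never look like a coordinate or a reserved token
    if esc in _RESERVED or _is_int(esc):
        esc = f"%{ord(esc[0]):02X}" + esc[1:]
    return esc


def _unescape(token: str) -> str:
    return urllib.parse.unquote(token)


def encode_scheme(scheme: ReactionScheme, n_bins: int = DEFAULT_BINS) -> TokenSequence:
    """Linearize: one RXN block per step; inside, reactants, conditions, products."""
    canvas = (scheme.canvas_width, scheme.canvas_height)
    tokens: list[str] = []
    for step in scheme.steps:
        tokens.append(RXN_START)
        for start, end, ids in (
            (RCT_START, RCT_END, step.reactant_ids),
            (CND_START, CND_END, step.condition_ids),
            (PRD_START, PRD_END, step.product_ids),
        ):
            for cid in ids:
                comp = scheme.component(cid)
                tokens.append(start)
                tokens.extend(str(q) for q in quantize_bbox(comp.bbox, canvas, n_bins))
                if comp.items is not None:
                    for item in comp.items:
                        if item.role in ROLE_TOKENS:
                            tokens.append(ROLE_TOKENS[item.role])
                        tokens.append(_escape(item.text))
                tokens.append(end)
        tokens.append(RXN_END)
    return TokenSequence(tokens, n_bins, *canvas)


# --------------------------------------------------------------------------
# decoding (total: diagnostics, never exceptions)


_START_OF = {RCT_START: "reactant", CND_START: "condition", PRD_START: "product"}
_END_OF = {RCT_START: RCT_END, CND_START: CND_END, PRD_START: PRD_END}


def _is_int(tok: str) -> bool:
    return tok.isdigit() or (tok.startswith("-") and tok[1:].isdigit())


def decode_tokens(
    seq: TokenSequence,
    canvas: Optional[tuple[float, float]] = None,
) -> tuple[ReactionScheme, list[str]]:
    """Parse a token stream back into a scheme skeleton.

    Well-formed input reproduces roles and texts exactly and boxes within
    quantization error; malformed input yields a partial scheme plus
    diagnostics.  Decoded condition items inherit their component's box
    (item sub-boxes are not part of the sequence format).
    """
    canvas = canvas or (seq.canvas_width, seq.canvas_height)
    n_bins = seq.n_bins
    toks = list(seq.tokens)
    diagnostics: list[str] = []
    components: list[Component] = []
    steps: list[ReactionStep] = []
    if not toks:
        diagnostics.append("empty token stream")

    i = 0
    n = len(toks)
    while i < n:
        tok = toks[i]
        if tok != RXN_START:
            diagnostics.append(f"token {i}: expected {RXN_START}, skipping {tok!r}")
            i += 1
            continue
        i += 1
        groups: dict[str, list[str]] = {"reactant": [], "condition": [], "product": []}
        closed = False
        while i < n:
            tok = toks[i]
            if tok == RXN_END:
                i += 1
                closed = True
                break
            if tok not in _START_OF:
                diagnostics.append(f"token {i}: unexpected {tok!r} inside reaction block")
                i += 1
                continue
            role = _START_OF[tok]
            end_tok = _END_OF[tok]
            i += 1
            coords: list[int] = []
            items: list[ConditionItem] = []
            pending_role: Optional[str] = None
            comp_closed = False
            while i < n and toks[i] not in (RXN_END, RXN_START):
                t = toks[i]
                if t == end_tok:
                    i += 1
                    comp_closed = True
                    break
                if t in _START_OF:
                    break  # unclosed block; let outer loop handle the new start
                if _is_int(t) and len(coords) < 4:
                    coords.append(int(t))
                elif t in TOKEN_ROLES:
                    if pending_role is not None:
                        diagnostics.append(f"token {i}: role token {t!r} without text, dropped")
                    pending_role = TOKEN_ROLES[t]
                elif t in STRUCTURAL_TOKENS:
                    diagnostics.append(f"token {i}: stray structural token {t!r}")
                else:
                    items.append(ConditionItem(_unescape(t), pending_role or "other", BBox(0, 0, 1, 1)))
                    pending_role = None
                i += 1
            if pending_role is not None:
                diagnostics.append(f"role token for {pending_role!r} had no text, dropped")
            if not comp_closed:
                diagnostics.append(f"unclosed component block ({role}), block dropped")
                continue
            if len(coords) != 4:
                diagnostics.append(f"component block ({role}) has {len(coords)} coordinates, dropped")
                continue
            bbox = dequantize_bbox(coords, canvas, n_bins)
            if not bbox.is_valid():
                diagnostics.append(f"component block ({role}) has degenerate box, kept as-is")
            cid = f"comp{len(components)}"
            if role == "condition":
                items = [ConditionItem(it.text, it.role, bbox) for it in items]
                components.append(Component(cid, role, bbox, items=items))
            else:
                components.append(Component(cid, role, bbox, smiles=None))
            groups[role].append(cid)
        if not closed:
            diagnostics.append("unclosed reaction block")
        if groups["reactant"] or groups["product"] or groups["condition"]:
            r_boxes = [components[int(c[4:])].bbox for c in groups["reactant"]]
            p_boxes = [components[int(c[4:])].bbox for c in groups["product"]]
            start = BBox.union(r_boxes).center if r_boxes else (0.0, 0.0)
            end = BBox.union(p_boxes).center if p_boxes else (canvas[0], canvas[1])
            if start == end:
                end = (start[0] + 1.0, start[1])
            steps.append(
                ReactionStep(groups["reactant"], groups["condition"], groups["product"],
                             Arrow(start, end))
            )
        else:
            diagnostics.append("reaction block with no components, dropped")
    scheme = ReactionScheme(canvas[0], canvas[1], components, steps, "single_line")
    return scheme, diagnostics
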