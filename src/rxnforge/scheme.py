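"""Core domain model for chemical reaction schemes.

A :class:`ReactionScheme` is the single source of truth behind a rendered
reaction-scheme image and its annotation: a canvas, a set of role-labelled,
axis-aligned components (reactant/product molecules and condition-text
regions), and the reaction steps (arrows) that connect them.  Coordinates are
pixels with the origin at the top-left corner; boxes are half-open on their
max edges, so ``width = x_max - x_min`` and IoU arithmetic is unambiguous.

Reaction SMILES follow the Daylight ``reactants>agents>products`` grammar
with ``.``-joined molecules per field.  Equality of two reaction SMILES is
defined on the canonical forms produced by a pluggable canonicalizer
(RDKit by default): the molecule *multisets* of each field must agree, so
atom numbering and within-field order are irrelevant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Literal, Optional, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # parse failures are handled as data/errors

ComponentRole = Literal["reactant", "condition", "product"]
ConditionRole = Literal["agent", "solvent", "temperature", "time", "yield", "other"]
ArrowKind = Literal["straight", "curved", "bidirectional"]
PatternName = Literal["single_line", "multiple_line", "branch", "cycle"]

COMPONENT_ROLES: tuple[str, ...] = ("reactant", "condition", "product")
CONDITION_ROLES: tuple[str, ...] = ("agent", "solvent", "temperature", "time", "yield", "other")
ARROW_KINDS: tuple[str, ...] = ("straight", "curved", "bidirectional")
PATTERNS: tuple[str, ...] = ("single_line", "multiple_line", "branch", "cycle")


class SchemeError(ValueError):
    """Hard error raised for unresolvable ids or unparseable molecule payloads."""


class ReactionParseError(SchemeError):
    """A reaction SMILES string could not be parsed."""


# --------------------------------------------------------------------------
# geometry


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box, half-open on the max edges: [x_min, x_max) x [y_min, y_max)."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return max(0.0, self.width) * max(0.0, self.height)

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def is_valid(self) -> bool:
        return self.x_min < self.x_max and self.y_min < self.y_max

    def translate(self, dx: float, dy: float) -> "BBox":
        return BBox(self.x_min + dx, self.y_min + dy, self.x_max + dx, self.y_max + dy)

    def round(self) -> "BBox":
        return BBox(
            int(math.floor(self.x_min)),
            int(math.floor(self.y_min)),
            int(math.ceil(self.x_max)),
            int(math.ceil(self.y_max)),
        )

    def contains(self, other: "BBox", slack: float = 0.0) -> bool:
        return (
            self.x_min - slack <= other.x_min
            and self.y_min - slack <= other.y_min
            and other.x_max <= self.x_max + slack
            and other.y_max <= self.y_max + slack
        )

    def intersection_area(self, other: "BBox") -> float:
        w = min(self.x_max, other.x_max) - max(self.x_min, other.x_min)
        h = min(self.y_max, other.y_max) - max(self.y_min, other.y_min)
        if w <= 0 or h <= 0:
            return 0.0
        return w * h

    def iou(self, other: "BBox") -> float:
        inter = self.intersection_area(other)
        if inter == 0.0:
            return 0.0
        union = self.area + other.area - inter
        return inter / union if union > 0 else 0.0

    @staticmethod
    def union(boxes: Sequence["BBox"]) -> "BBox":
        if not boxes:
            raise ValueError("union of zero boxes")
        return BBox(
            min(b.x_min for b in boxes),
            min(b.y_min for b in boxes),
            max(b.x_max for b in boxes),
            max(b.y_max for b in boxes),
        )


@dataclass(frozen=True)
class ConditionItem:
    """One rendered condition text span with its semantic role.

    ``role="other"`` marks auxiliary text (e.g. "pH 10-11", R-group legends)
    outside the five core roles; such items carry no role token when the
    annotation is serialized to a token sequence.
    """

    text: str
    role: str
    bbox: BBox


@dataclass
class Component:
    """A localized scheme region: a molecule (reactant/product) or condition text block."""

    id: str
    role: str
    bbox: BBox
    smiles: Optional[str] = None
    items: Optional[list[ConditionItem]] = None

    @property
    def is_molecule(self) -> bool:
        return self.role in ("reactant", "product")


@dataclass(frozen=True)
class Arrow:
    start: tuple[float, float]
    end: tuple[float, float]
    kind: str = "straight"
    crossed_out: bool = False
    control_points: tuple[tuple[float, float], ...] = ()

    @property
    def midpoint(self) -> tuple[float, float]:
        if self.kind == "curved" and self.control_points:
            # the drawn path passes through the control points; use the middle one
            mid = self.control_points[len(self.control_points) // 2]
            return (float(mid[0]), float(mid[1]))
        return (
            (self.start[0] + self.end[0]) / 2.0,
            (self.start[1] + self.end[1]) / 2.0,
        )


@dataclass
class ReactionStep:
    reactant_ids: list[str]
    condition_ids: list[str]
    product_ids: list[str]
    arrow: Arrow


@dataclass
class ReactionScheme:
    canvas_width: float
    canvas_height: float
    components: list[Component]
    steps: list[ReactionStep]
    pattern: str
    # drawn-but-not-annotated glyphs ("+" between co-reactants); not components
    decorations: list[tuple[str, BBox]] = field(default_factory=list)

    def component(self, cid: str) -> Component:
        for c in self.components:
            if c.id == cid:
                return c
        raise SchemeError(f"unresolved component id {cid!r}")

    def has_component(self, cid: str) -> bool:
        return any(c.id == cid for c in self.components)

    def molecule_components(self) -> list[Component]:
        return [c for c in self.components if c.is_molecule]

    def condition_items(self) -> list[ConditionItem]:
        out: list[ConditionItem] = []
        for c in self.components:
            if c.items:
                out.extend(c.items)
        return out


# --------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Violation:
    entity: str
    rule: str
    message: str


def _smiles_parses(smiles: Optional[str]) -> bool:
    if not smiles:
        return False
    return Chem.MolFromSmiles(smiles) is not None


def validate_scheme(scheme: ReactionScheme) -> list[Violation]:
    """Check every structural invariant; violations are data, never exceptions."""
    v: list[Violation] = []
    canvas = BBox(0, 0, max(scheme.canvas_width, 1e-9), max(scheme.canvas_height, 1e-9))
    if scheme.pattern not in PATTERNS:
        v.append(Violation("scheme", "unknown pattern", f"pattern {scheme.pattern!r}"))

    seen: set[str] = set()
    for c in scheme.components:
        ent = f"component {c.id}"
        if c.id in seen:
            v.append(Violation(ent, "duplicate id", f"id {c.id!r} not unique"))
        seen.add(c.id)
        if c.role not in COMPONENT_ROLES:
            v.append(Violation(ent, "unknown role", f"role {c.role!r}"))
        if not c.bbox.is_valid():
            v.append(Violation(ent, "degenerate bbox", f"{c.bbox}"))
        elif not canvas.contains(c.bbox, slack=1e-6):
            v.append(Violation(ent, "bbox outside canvas", f"{c.bbox}"))
        if c.role == "condition":
            if c.items is None or c.smiles is not None:
                v.append(Violation(ent, "payload mismatch", "condition component must carry items"))
            else:
                for i, item in enumerate(c.items):
                    ient = f"{ent} item {i}"
                    if not item.text:
                        v.append(Violation(ient, "empty text", "condition text must be non-empty"))
                    if item.role not in CONDITION_ROLES:
                        v.append(Violation(ient, "unknown condition role", f"role {item.role!r}"))
                    if not item.bbox.is_valid():
                        v.append(Violation(ient, "degenerate bbox", f"{item.bbox}"))
                    elif not c.bbox.contains(item.bbox, slack=1e-6):
                        v.append(Violation(ient, "item outside component", f"{item.bbox}"))
        else:
            if c.items is not None or c.smiles is None:
                v.append(Violation(ent, "payload mismatch", "molecule component must carry SMILES"))
            elif not _smiles_parses(c.smiles):
                v.append(Violation(ent, "invalid SMILES", f"payload {c.smiles!r} does not parse"))

    referenced: set[str] = set()
    for si, s in enumerate(scheme.steps):
        ent = f"step {si}"
        if not s.reactant_ids:
            v.append(Violation(ent, "step missing reactant", "reactant_ids empty"))
        if not s.product_ids:
            v.append(Violation(ent, "step missing product", "product_ids empty"))
        for group, ids, want_mol in (
            ("reactant_ids", s.reactant_ids, True),
            ("condition_ids", s.condition_ids, False),
            ("product_ids", s.product_ids, True),
        ):
            for cid in ids:
                referenced.add(cid)
                if not scheme.has_component(cid):
                    v.append(Violation(ent, "unresolved id", f"{group} references {cid!r}"))
                    continue
                comp = scheme.component(cid)
                if want_mol and not comp.is_molecule:
                    v.append(Violation(ent, "role mismatch", f"{group} references condition {cid!r}"))
                if not want_mol and comp.is_molecule:
                    v.append(Violation(ent, "role mismatch", f"{group} references molecule {cid!r}"))
        a = s.arrow
        if a.start == a.end:
            v.append(Violation(ent, "degenerate arrow", "start == end"))
        if a.kind not in ARROW_KINDS:
            v.append(Violation(ent, "unknown arrow kind", f"kind {a.kind!r}"))
        if a.kind == "curved" and not a.control_points:
            v.append(Violation(ent, "curved arrow without control points", ""))

    for c in scheme.components:
        if c.id not in referenced:
            v.append(Violation(f"component {c.id}", "orphan component", "referenced by no step"))
    return v


# --------------------------------------------------------------------------
# reaction SMILES assembly and equality

Canonicalizer = Callable[[str], str]


def rdkit_canonicalizer(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ReactionParseError(f"SMILES {smiles!r} does not parse")
    return Chem.MolToSmiles(mol)


def agent_smiles_items(scheme: ReactionScheme, step: ReactionStep) -> list[str]:
    """SMILES-valued agent condition items of a step, in component/item order.

    Name-only agents (e.g. "Pd/C") stay metadata: only texts that parse as
    SMILES enter the agent field of the assembled reaction.
    """
    out: list[str] = []
    for cid in step.condition_ids:
        comp = scheme.component(cid)
        for item in comp.items or []:
            if item.role == "agent" and _smiles_parses(item.text):
                out.append(item.text)
    return out


def assemble_reaction_smiles(
    step: ReactionStep, scheme: ReactionScheme, include_agents: bool = True
) -> str:
    """Join a step's molecule payloads into ``r1.r2>a1.a2>p1.p2``."""
    fields: list[list[str]] = [[], [], []]
    for idx, ids in ((0, step.reactant_ids), (2, step.product_ids)):
        for cid in ids:
            comp = scheme.component(cid)  # raises SchemeError on dangling id
            if comp.smiles is None:
                raise SchemeError(f"component {cid!r} carries no molecule payload")
            if not _smiles_parses(comp.smiles):
                raise SchemeError(f"payload {comp.smiles!r} of {cid!r} does not parse")
            fields[idx].append(comp.smiles)
    if include_agents:
        fields[1] = agent_smiles_items(scheme, step)
    return ">".join(".".join(f) for f in fields)


def split_reaction_smiles(reaction: str) -> tuple[list[str], list[str], list[str]]:
    parts = reaction.split(">")
    if len(parts) != 3:
        raise ReactionParseError(
            f"reaction SMILES needs exactly two '>' separators: {reaction!r}"
        )
    return tuple([m for m in p.split(".") if m] for p in parts)  # type: ignore[return-value]


def canonical_reaction(
    reaction: str,
    canonicalizer: Canonicalizer = rdkit_canonicalizer,
    compare_agents: bool = True,
) -> tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]:
    """Canonical multiset key of a reaction: sorted canonical SMILES per field."""
    r, a, p = split_reaction_smiles(reaction)
    if not compare_agents:
        a = []
    return (
        tuple(sorted(canonicalizer(m) for m in r)),
        tuple(sorted(canonicalizer(m) for m in a)),
        tuple(sorted(canonicalizer(m) for m in p)),
    )


def reaction_equal(
    a: str,
    b: str,
    canonicalizer: Canonicalizer = rdkit_canonicalizer,
    compare_agents: bool = True,
) -> bool:
    """True iff the canonical molecule multisets of each field agree pairwise."""
    try:
        ka = canonical_reaction(a, canonicalizer, compare_agents)
    except ReactionParseError as e:
        raise ReactionParseError(f"left reaction failed to parse: {e}") from e
    try:
        kb = canonical_reaction(b, canonicalizer, compare_agents)
    except ReactionParseError as e:
        raise ReactionParseError(f"right reaction failed to parse: {e}") from e
    return ka == kb


def expand_bidirectional(scheme: ReactionScheme) -> ReactionScheme:
    """Resolve arrow semantics for reaction assembly.

    Bidirectional (equilibrium) arrows become two straight-arrow steps, one
    per direction; crossed-out arrows mark reactions that do not occur and
    are dropped.  Idempotent: the output contains neither kind.
    """
    steps: list[ReactionStep] = []
    for s in scheme.steps:
        if s.arrow.crossed_out:
            continue
        if s.arrow.kind == "bidirectional":
            fwd = Arrow(s.arrow.start, s.arrow.end, "straight", False, s.arrow.control_points)
            rev = Arrow(s.arrow.end, s.arrow.start, "straight", False, s.arrow.control_points)
            steps.append(ReactionStep(list(s.reactant_ids), list(s.condition_ids), list(s.product_ids), fwd))
            steps.append(ReactionStep(list(s.product_ids), list(s.condition_ids), list(s.reactant_ids), rev))
        else:
            steps.append(ReactionStep(list(s.reactant_ids), list(s.condition_ids), list(s.product_ids), s.arrow))
    return ReactionScheme(
        canvas_width=scheme.canvas_width,
        canvas_height=scheme.canvas_height,
        components=list(scheme.components),
        steps=steps,
        pattern=scheme.pattern,
        decorations=list(scheme.decorations),
    )
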