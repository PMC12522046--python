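"""End-to-end synthesis of one annotated reaction-scheme image.

Pipeline per image: draw a concrete style (font, line width, molecule scale,
pattern), plan the reaction steps for that pattern from a reaction source,
sample condition text for every arrow, lay the scheme out, and rasterize.
SMILES-valued agents of the source reaction are placed above the arrow as
agent condition items, so the reaction SMILES assembled back from the
annotation is always equivalent to the per-step source reaction.

Branch and cycle topologies recombine molecules from the source (a branch
shares the reactant set of its group; a cycle chains single-molecule nodes
into a closed loop); the recorded per-step ground-truth reaction is the
recombined reaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from PIL import Image

from .conditions import _SENTINEL, ConditionItem, ConditionSpec, sample_conditions
from .depict import RDKitDepictor
from .layout import LayoutStep, layout_scheme
from .render import render_scheme
from .reactions import ReactionInput, ReactionSourceLike, parse_reaction_smiles
from .rng import RNGStream
from .scheme import ReactionScheme
from .style import StyleConfig, StyleDraw, draw_style


@dataclass
class GeneratedScheme:
    scheme: ReactionScheme
    draw: StyleDraw
    step_sources: list[str]          # per-step ground-truth reaction SMILES
    image: Optional[Image.Image] = None


def plan_steps(
    pattern: str,
    source: ReactionSourceLike,
    cond_spec: ConditionSpec,
    rng: RNGStream,
) -> list[LayoutStep]:
    """Choose reactions and condition text realizing ``pattern``."""
    g = rng.generator()
    reactions: list[ReactionInput]
    if pattern == "single_line":
        if g.random() < 0.7:
            reactions = [parse_reaction_smiles(source.draw(rng.child(1)))]
        else:  # chained two-step line A -> B -> C
            nodes = source.draw_chain_nodes(rng.child(1), 3)
            reactions = [
                parse_reaction_smiles(f"{nodes[i]}>>{nodes[i + 1]}") for i in range(2)
            ]
    elif pattern == "multiple_line":
        n = int(g.integers(2, 4))
        reactions = [
            parse_reaction_smiles(source.draw(rng.child(1, i))) for i in range(n)
        ]
    elif pattern == "branch":
        k = int(g.integers(2, 4))
        reactions = [parse_reaction_smiles(r) for r in source.draw_group(rng.child(1), k)]
    elif pattern == "cycle":
        k = int(g.integers(3, 6))
        nodes = source.draw_chain_nodes(rng.child(1), k)
        reactions = [
            parse_reaction_smiles(f"{nodes[i]}>>{nodes[(i + 1) % k]}") for i in range(k)
        ]
    else:
        raise ValueError(f"unknown pattern {pattern!r}")

    steps: list[LayoutStep] = []
    for i, rxn in enumerate(reactions):
        items = sample_conditions(rng.child(2, i), cond_spec)
        # the source's own agents ride above the arrow as SMILES-valued items
        items = [ConditionItem(a, "agent", _SENTINEL) for a in rxn.agents] + items
        steps.append(LayoutStep(rxn, items))
    return steps


def generate_scheme(
    source: ReactionSourceLike,
    style: StyleConfig,
    cond_spec: ConditionSpec,
    rng: RNGStream,
    pattern: Optional[str] = None,
    render: bool = True,
    depictor: Optional[RDKitDepictor] = None,
) -> GeneratedScheme:
    """Generate one annotated scheme; rendering optional (layout-only is fast)."""
    depictor = depictor or RDKitDepictor()
    draw = draw_style(style, rng.child(0))
    if pattern is not None:
        draw = StyleDraw(
            draw.font_size, draw.line_width, draw.molecule_scale,
            pattern, draw.font_path, draw.rotation,
        )
    steps = plan_steps(draw.pattern, source, cond_spec, rng)
    scheme = layout_scheme(steps, draw.pattern, style, draw, depictor)
    sources = [s.reaction.raw for s in steps]
    if not render:
        return GeneratedScheme(scheme, draw, sources)
    image, final = render_scheme(scheme, draw, depictor)
    return GeneratedScheme(final, draw, sources, image)
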