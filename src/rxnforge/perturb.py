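"""Controlled corruption of ground-truth schemes into imperfect predictions.

Used to exercise the evaluator: role relabeling (including the agent-as-
reactant relabeling that separates soft from hard match), bounding-box
jitter, step deletion and spurious step insertion, condition-item role flips
and text typos.  All corruption is seed-deterministic.
"""

from __future__ import annotations

import copy
from dataclasses import replace
from typing import Optional

from .rng import RNGStream
from .scheme import BBox, Component, ConditionItem, ReactionScheme, ReactionStep


def _clone(scheme: ReactionScheme) -> ReactionScheme:
    return copy.deepcopy(scheme)


def relabel_agent_as_reactant(scheme: ReactionScheme, step_index: int = 0) -> ReactionScheme:
    """Move a molecular-agent condition of one step into its reactant set.

    This is exactly the relabeling the soft criterion forgives: soft metrics
    stay perfect while hard metrics drop.  Returns the corrupted copy, or
    None-equivalent (unchanged copy) if the step has no agent condition.
    """
    from .evaluate import is_agent_molecule

    out = _clone(scheme)
    step = out.steps[step_index]
    for cid in list(step.condition_ids):
        comp = out.component(cid)
        if is_agent_molecule(comp):
            step.condition_ids.remove(cid)
            step.reactant_ids.append(cid)
            comp.role = "reactant"
            return out
    return out


def jitter_boxes(scheme: ReactionScheme, rng: RNGStream, max_shift: float = 4.0) -> ReactionScheme:
    """Shift every box by up to ``max_shift`` px per edge (stays IoU > 0.5 for
    typical component sizes, so matches survive; larger shifts break them)."""
    g = rng.generator()
    out = _clone(scheme)
    for comp in out.components:
        dx, dy = g.uniform(-max_shift, max_shift, size=2)
        comp.bbox = comp.bbox.translate(float(dx), float(dy))
        if comp.items is not None:
            comp.items = [replace(i, bbox=i.bbox.translate(float(dx), float(dy))) for i in comp.items]
    return out


def delete_step(scheme: ReactionScheme, step_index: int) -> ReactionScheme:
    out = _clone(scheme)
    del out.steps[step_index]
    return out


def insert_bogus_step(scheme: ReactionScheme, rng: RNGStream) -> ReactionScheme:
    """Duplicate a step with heavily jittered boxes (a confident false positive)."""
    g = rng.generator()
    out = _clone(scheme)
    src = out.steps[int(g.integers(len(out.steps)))]
    new_ids = []
    for cid in (*src.reactant_ids, *src.product_ids):
        comp = out.component(cid)
        shift = float(g.uniform(150, 400))
        nid = f"{comp.id}_fp{len(out.components)}"
        out.components.append(
            Component(nid, comp.role, comp.bbox.translate(shift, shift), smiles=comp.smiles)
        )
        new_ids.append(nid)
    k = len(src.reactant_ids)
    out.steps.append(
        ReactionStep(new_ids[:k], [], new_ids[k:],
                     replace(src.arrow, start=(src.arrow.start[0] + 1, src.arrow.start[1])))
    )
    return out


def flip_condition_roles(scheme: ReactionScheme, rng: RNGStream, p_flip: float = 0.3) -> ReactionScheme:
    from .scheme import CONDITION_ROLES

    g = rng.generator()
    out = _clone(scheme)
    for comp in out.components:
        if comp.items is None:
            continue
        new_items = []
        for item in comp.items:
            if g.random() < p_flip:
                others = [r for r in CONDITION_ROLES if r != item.role]
                item = replace(item, role=others[int(g.integers(len(others)))])
            new_items.append(item)
        comp.items = new_items
    return out


def typo_texts(scheme: ReactionScheme, rng: RNGStream, p_typo: float = 0.3) -> ReactionScheme:
    g = rng.generator()
    out = _clone(scheme)
    for comp in out.components:
        if comp.items is None:
            continue
        comp.items = [
            replace(i, text=i.text + "~") if g.random() < p_typo else i
            for i in comp.items
        ]
    return out


def random_corruption(scheme: ReactionScheme, rng: RNGStream) -> ReactionScheme:
    """Apply a random combination of corruptions (at least one)."""
    g = rng.generator()
    out = _clone(scheme)
    applied = False
    if g.random() < 0.5:
        out = relabel_agent_as_reactant(out, int(g.integers(len(out.steps))))
        applied = True
    if g.random() < 0.5:
        out = jitter_boxes(out, rng.child(1), max_shift=float(g.uniform(2, 40)))
        applied = True
    if len(out.steps) > 1 and g.random() < 0.3:
        out = delete_step(out, int(g.integers(len(out.steps))))
        applied = True
    if g.random() < 0.3:
        out = insert_bogus_step(out, rng.child(2))
        applied = True
    if g.random() < 0.4:
        out = flip_condition_roles(out, rng.child(3))
        applied = True
    if not applied:
        out = jitter_boxes(out, rng.child(4), max_shift=60.0)
    return out
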