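"""Scoring of reaction-image parser predictions against ground truth.

Reaction-level metrics use hard and soft match criteria: a predicted
reaction counts only when a one-to-one correspondence exists between its
components and the ground-truth step's components with box IoU >= tau and
agreeing roles.  *Hard* match requires role identity; *soft* match relaxes
exactly one thing — a ground-truth molecular agent (a condition region
whose agent text parses as SMILES) may be predicted as a reactant.  Since
every hard correspondence is also a soft one, soft precision/recall/F1
dominate hard everywhere.

Step matching across a scheme is maximum-cardinality bipartite matching on
the boolean step-compatibility graph (Kuhn's augmenting paths, ties broken
by input order).  Condition-level metrics (role identification, OCR) pair
text items greedily by highest item-box IoU and score the paired roles and
normalized texts; reaction-SMILES accuracy is the fraction of images whose
full predicted reaction set is equivalent to ground truth under canonical
multiset equality.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from rdkit import Chem

from .scheme import (
    CONDITION_ROLES,
    BBox,
    Component,
    ConditionItem,
    ReactionParseError,
    ReactionScheme,
    ReactionStep,
    canonical_reaction,
)

logger = logging.getLogger("rxnforge")

MatchMode = Literal["hard", "soft"]
DEFAULT_IOU = 0.5


# --------------------------------------------------------------------------
# matching machinery


def max_bipartite_matching(adjacency: Sequence[Sequence[bool]]) -> list[tuple[int, int]]:
    """Maximum-cardinality matching via augmenting paths; deterministic order."""
    n_left = len(adjacency)
    n_right = len(adjacency[0]) if n_left else 0
    match_right: list[Optional[int]] = [None] * n_right

    def try_augment(u: int, seen: list[bool]) -> bool:
        for v in range(n_right):
            if adjacency[u][v] and not seen[v]:
                seen[v] = True
                if match_right[v] is None or try_augment(match_right[v], seen):
                    match_right[v] = u
                    return True
        return False

    for u in range(n_left):
        try_augment(u, [False] * n_right)
    return sorted((u, v) for v, u in enumerate(match_right) if u is not None)  # type: ignore[misc]


# --------------------------------------------------------------------------
# component / step matching


def is_agent_molecule(comp: Component) -> bool:
    """A condition region standing for a molecular agent drawn at the arrow."""
    if comp.role != "condition":
        return False
    return any(
        i.role == "agent" and Chem.MolFromSmiles(i.text) is not None
        for i in comp.items or []
    )


def _context_role(comp: Component, step: Optional[ReactionStep]) -> str:
    """Role of a component within a step (which id-list it sits in)."""
    if step is not None:
        if comp.id in step.reactant_ids:
            return "reactant"
        if comp.id in step.condition_ids:
            return "condition"
        if comp.id in step.product_ids:
            return "product"
    return comp.role


def component_matches(
    pred: Component,
    gt: Component,
    mode: MatchMode = "hard",
    iou_threshold: float = DEFAULT_IOU,
    pred_role: Optional[str] = None,
    gt_role: Optional[str] = None,
) -> bool:
    """Boxes correspond (IoU >= tau) and roles agree under the match mode."""
    if pred.bbox.iou(gt.bbox) < iou_threshold:
        return False
    pr = pred_role or pred.role
    gr = gt_role or gt.role
    if pr == gr:
        return True
    if mode == "soft" and pr == "reactant" and gr == "condition" and is_agent_molecule(gt):
        return True
    return False


def step_matches(
    pred_step: ReactionStep,
    pred_scheme: ReactionScheme,
    gt_step: ReactionStep,
    gt_scheme: ReactionScheme,
    mode: MatchMode = "hard",
    iou_threshold: float = DEFAULT_IOU,
) -> bool:
    """True iff a component bijection exists respecting roles under ``mode``."""
    pred_comps = [
        (pred_scheme.component(c), role)
        for role, ids in (
            ("reactant", pred_step.reactant_ids),
            ("condition", pred_step.condition_ids),
            ("product", pred_step.product_ids),
        )
        for c in ids
    ]
    gt_comps = [
        (gt_scheme.component(c), role)
        for role, ids in (
            ("reactant", gt_step.reactant_ids),
            ("condition", gt_step.condition_ids),
            ("product", gt_step.product_ids),
        )
        for c in ids
    ]
    if len(pred_comps) != len(gt_comps):
        return False
    adjacency = [
        [
            component_matches(pc, gc, mode, iou_threshold, pred_role=pr, gt_role=gr)
            for gc, gr in gt_comps
        ]
        for pc, pr in pred_comps
    ]
    return len(max_bipartite_matching(adjacency)) == len(gt_comps)


# --------------------------------------------------------------------------
# reaction-level metrics


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    mode: str
    iou_threshold: float
    pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def precision(self) -> float:
        n_pred = self.tp + self.fp
        return self.tp / n_pred if n_pred else 0.0

    @property
    def recall(self) -> float:
        n_gt = self.tp + self.fn
        return self.tp / n_gt if n_gt else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "mode": self.mode, "iou_threshold": self.iou_threshold,
        }


def match_reactions(
    preds: Sequence[tuple[ReactionStep, ReactionScheme]],
    gts: Sequence[tuple[ReactionStep, ReactionScheme]],
    mode: MatchMode = "hard",
    iou_threshold: float = DEFAULT_IOU,
) -> MatchResult:
    """Maximum-cardinality one-to-one matching between predicted and gt steps."""
    adjacency = [
        [
            step_matches(ps, psch, gs, gsch, mode, iou_threshold)
            for gs, gsch in gts
        ]
        for ps, psch in preds
    ]
    pairs = max_bipartite_matching(adjacency) if preds and gts else []
    tp = len(pairs)
    return MatchResult(
        tp=tp, fp=len(preds) - tp, fn=len(gts) - tp,
        mode=mode, iou_threshold=iou_threshold, pairs=pairs,
    )


def _scheme_steps(scheme: ReactionScheme) -> list[tuple[ReactionStep, ReactionScheme]]:
    return [(s, scheme) for s in scheme.steps]


def evaluate_by_pattern(
    predictions: dict[str, ReactionScheme],
    ground_truth: dict[str, ReactionScheme],
    patterns: dict[str, str],
    mode: MatchMode = "hard",
    iou_threshold: float = DEFAULT_IOU,
) -> dict[str, MatchResult]:
    """Per-pattern results plus a pooled 'overall' (counts add across patterns)."""
    from .scheme import PATTERNS

    per_image: dict[str, MatchResult] = {}
    for image_id, gt in ground_truth.items():
        pred = predictions.get(image_id)
        per_image[image_id] = match_reactions(
            _scheme_steps(pred) if pred else [], _scheme_steps(gt), mode, iou_threshold
        )
    out: dict[str, MatchResult] = {}
    buckets: dict[str, list[str]] = {}
    for image_id in ground_truth:
        tag = patterns[image_id]
        if tag not in PATTERNS:
            raise ValueError(f"unknown pattern tag {tag!r} for image {image_id!r}")
        buckets.setdefault(tag, []).append(image_id)
    for tag, ids in sorted(buckets.items()):
        out[tag] = MatchResult(
            tp=sum(per_image[i].tp for i in ids),
            fp=sum(per_image[i].fp for i in ids),
            fn=sum(per_image[i].fn for i in ids),
            mode=mode, iou_threshold=iou_threshold,
        )
    out["overall"] = MatchResult(
        tp=sum(r.tp for k, r in out.items()),
        fp=sum(r.fp for k, r in out.items()),
        fn=sum(r.fn for k, r in out.items()),
        mode=mode, iou_threshold=iou_threshold,
    )
    return out


# --------------------------------------------------------------------------
# condition-level metrics


def pair_items(
    pred_items: Sequence[ConditionItem],
    gt_items: Sequence[ConditionItem],
    iou_threshold: float = DEFAULT_IOU,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy highest-IoU-first pairing of text regions.

    Returns (pairs, unpaired_pred_indices, unpaired_gt_indices).
    """
    candidates = []
    for i, p in enumerate(pred_items):
        for j, g in enumerate(gt_items):
            iou = p.bbox.iou(g.bbox)
            if iou >= iou_threshold:
                candidates.append((-iou, i, j))
    candidates.sort()
    used_p: set[int] = set()
    used_g: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if i in used_p or j in used_g:
            continue
        pairs.append((i, j))
        used_p.add(i)
        used_g.add(j)
    unpaired_p = [i for i in range(len(pred_items)) if i not in used_p]
    unpaired_g = [j for j in range(len(gt_items)) if j not in used_g]
    return pairs, unpaired_p, unpaired_g


MISSED = "missed"
CONFUSION_COLUMNS = (*CONDITION_ROLES, MISSED)


@dataclass
class ConfusionMatrix:
    """Role confusion over the six condition roles.

    Rows are ground-truth roles, columns predicted roles plus a dedicated
    ``missed`` column for unpaired ground-truth items; unpaired predictions
    count into the ``other`` row.  Accuracy is the 6x6 trace over the total.
    """

    counts: dict[str, dict[str, int]]
    iou_threshold: float

    @property
    def total(self) -> int:
        return sum(sum(row.values()) for row in self.counts.values())

    @property
    def accuracy(self) -> float:
        trace = sum(self.counts[r][r] for r in CONDITION_ROLES)
        return trace / self.total if self.total else 0.0

    def per_role(self) -> dict[str, dict[str, float]]:
        out = {}
        for role in CONDITION_ROLES:
            tp = self.counts[role][role]
            n_pred = sum(self.counts[g][role] for g in CONDITION_ROLES)
            n_gt = sum(self.counts[role].values())
            p = tp / n_pred if n_pred else 0.0
            r = tp / n_gt if n_gt else 0.0
            f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
            out[role] = {"precision": p, "recall": r, "f1": f1}
        return out

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [[self.counts[g][p] for p in CONFUSION_COLUMNS] for g in CONDITION_ROLES],
            index=list(CONDITION_ROLES),
            columns=list(CONFUSION_COLUMNS),
        )


def evaluate_cri(
    pred_items: Sequence[ConditionItem],
    gt_items: Sequence[ConditionItem],
    iou_threshold: float = DEFAULT_IOU,
) -> ConfusionMatrix:
    """Condition role identification: confusion over paired text regions."""
    counts = {g: {p: 0 for p in CONFUSION_COLUMNS} for g in CONDITION_ROLES}
    pairs, unpaired_p, unpaired_g = pair_items(pred_items, gt_items, iou_threshold)
    for i, j in pairs:
        counts[gt_items[j].role][pred_items[i].role] += 1
    for j in unpaired_g:
        counts[gt_items[j].role][MISSED] += 1
    for i in unpaired_p:
        counts["other"][pred_items[i].role] += 1
    return ConfusionMatrix(counts, iou_threshold)


def evaluate_cri_dataset(
    predictions: dict[str, ReactionScheme],
    ground_truth: dict[str, ReactionScheme],
    iou_threshold: float = DEFAULT_IOU,
) -> ConfusionMatrix:
    """CRI over a dataset: items are paired within each image, counts summed."""
    counts = {g: {p: 0 for p in CONFUSION_COLUMNS} for g in CONDITION_ROLES}
    for image_id, gt in ground_truth.items():
        pred = predictions.get(image_id)
        cm = evaluate_cri(
            pred.condition_items() if pred else [], gt.condition_items(), iou_threshold
        )
        for g in CONDITION_ROLES:
            for p in CONFUSION_COLUMNS:
                counts[g][p] += cm.counts[g][p]
    return ConfusionMatrix(counts, iou_threshold)


def ocr_accuracy_dataset(
    predictions: dict[str, ReactionScheme],
    ground_truth: dict[str, ReactionScheme],
    iou_threshold: float = DEFAULT_IOU,
) -> float:
    """Dataset OCR accuracy: pairs formed within each image, pooled fraction."""
    hits = 0
    total = 0
    for image_id, gt in ground_truth.items():
        pred = predictions.get(image_id)
        pred_items = pred.condition_items() if pred else []
        gt_items = gt.condition_items()
        pairs, _, _ = pair_items(pred_items, gt_items, iou_threshold)
        total += len(pairs)
        hits += sum(
            normalize_text(pred_items[i].text) == normalize_text(gt_items[j].text)
            for i, j in pairs
        )
    return hits / total if total else 0.0


def normalize_text(text: str) -> str:
    """OCR-equality normalization: NFKC, strip whitespace, unify degree glyphs."""
    t = unicodedata.normalize("NFKC", text)
    t = "".join(t.split())
    t = t.replace("℃", "°C").replace("°", "")
    return t


def ocr_accuracy(
    pred_items: Sequence[ConditionItem],
    gt_items: Sequence[ConditionItem],
    iou_threshold: float = DEFAULT_IOU,
) -> float:
    """Fraction of paired items whose normalized texts agree; 0 if nothing pairs."""
    pairs, _, _ = pair_items(pred_items, gt_items, iou_threshold)
    if not pairs:
        return 0.0
    hits = sum(
        normalize_text(pred_items[i].text) == normalize_text(gt_items[j].text)
        for i, j in pairs
    )
    return hits / len(pairs)


# --------------------------------------------------------------------------
# reaction SMILES exact-match accuracy


def smiles_exact_match_accuracy(
    pred_reactions: Sequence[Sequence[str]],
    gt_reactions: Sequence[Sequence[str]],
    compare_agents: bool = True,
) -> float:
    """Per-image exact match of the full reaction set (order-insensitive)."""
    if len(pred_reactions) != len(gt_reactions):
        raise ValueError("prediction and ground-truth lists differ in length")
    if not gt_reactions:
        return 0.0
    hits = 0
    for preds, gts in zip(pred_reactions, gt_reactions):
        try:
            pk = sorted(canonical_reaction(r, compare_agents=compare_agents) for r in preds)
        except ReactionParseError as e:
            logger.warning("unparseable prediction counts as non-match: %s", e)
            continue
        gk = sorted(canonical_reaction(r, compare_agents=compare_agents) for r in gts)
        if pk == gk:
            hits += 1
    return hits / len(gt_reactions)
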