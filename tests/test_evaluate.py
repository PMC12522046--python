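"""Evaluator: hard/soft matching, reaction-level P/R/F1, CRI, OCR, SMILES accuracy."""

import itertools

import numpy as np
import pytest

from rxnforge.evaluate import (
    ConfusionMatrix,
    component_matches,
    evaluate_by_pattern,
    evaluate_cri,
    match_reactions,
    max_bipartite_matching,
    normalize_text,
    ocr_accuracy,
    smiles_exact_match_accuracy,
    step_matches,
)
from rxnforge.perturb import relabel_agent_as_reactant
from rxnforge.scheme import (
    Arrow,
    BBox,
    Component,
    ConditionItem,
    ReactionScheme,
    ReactionStep,
)


def mol(cid, role, x, y, w=50, h=40, smiles="CCO"):
    return Component(cid, role, BBox(x, y, x + w, y + h), smiles=smiles)


def agent_condition(cid, x, y, text="[H+]"):
    box = BBox(x, y, x + 40, y + 15)
    return Component(cid, "condition", box, items=[ConditionItem(text, "agent", box)])


def one_step_scheme(offset=0.0, agent=True):
    comps = [
        mol("r0", "reactant", 10 + offset, 100 + offset),
        mol("p0", "product", 300 + offset, 100 + offset, smiles="CC=O"),
    ]
    cond_ids = []
    if agent:
        comps.append(agent_condition("c0", 150 + offset, 70 + offset))
        cond_ids = ["c0"]
    step = ReactionStep(["r0"], cond_ids, ["p0"], Arrow((70, 120), (290, 120)))
    return ReactionScheme(600, 400, comps, [step], "single_line")


class TestComponentMatches:
    def test_identical_component_matches_in_both_modes(self):
        a = mol("x", "reactant", 10, 10)
        assert component_matches(a, a, "hard")
        assert component_matches(a, a, "soft")

    def test_agent_molecule_as_reactant_soft_only(self):
        gt = agent_condition("c", 100, 100)
        pred = Component("q", "reactant", gt.bbox, smiles="[H+]")
        assert not component_matches(pred, gt, "hard")
        assert component_matches(pred, gt, "soft")

    def test_name_only_agent_gets_no_relaxation(self):
        box = BBox(0, 0, 40, 15)
        gt = Component("c", "condition", box,
                       items=[ConditionItem("Pd/C", "agent", box)])
        pred = Component("q", "reactant", box, smiles="CCO")
        assert not component_matches(pred, gt, "soft")

    def test_disjoint_boxes_never_match(self):
        a = mol("x", "reactant", 0, 0)
        b = mol("y", "reactant", 500, 300)
        assert not component_matches(a, b, "hard")
        assert not component_matches(a, b, "soft")


class TestStepMatches:
    def test_identical_step(self):
        s = one_step_scheme()
        assert step_matches(s.steps[0], s, s.steps[0], s, "hard")
        assert step_matches(s.steps[0], s, s.steps[0], s, "soft")

    def test_missing_product_fails_both_modes(self):
        gt = one_step_scheme()
        pred = one_step_scheme()
        pred.steps[0].product_ids = []
        pred.components = [c for c in pred.components if c.id != "p0"]
        assert not step_matches(pred.steps[0], pred, gt.steps[0], gt, "hard")
        assert not step_matches(pred.steps[0], pred, gt.steps[0], gt, "soft")

    def test_agent_moved_to_reactants_soft_only(self):
        gt = one_step_scheme()
        pred = relabel_agent_as_reactant(gt)
        assert pred.steps[0].reactant_ids == ["r0", "c0"]
        assert not step_matches(pred.steps[0], pred, gt.steps[0], gt, "hard")
        assert step_matches(pred.steps[0], pred, gt.steps[0], gt, "soft")


def k_step_scheme(k, match_mask=None):
    """k far-apart steps; match_mask selects which ones keep gt geometry."""
    comps, steps = [], []
    for i in range(k):
        dy = 0 if (match_mask is None or match_mask[i]) else 190  # break IoU
        comps.append(mol(f"r{i}", "reactant", 10, 100 + 400 * i + dy))
        comps.append(mol(f"p{i}", "product", 300, 100 + 400 * i + dy, smiles="CC=O"))
        steps.append(
            ReactionStep([f"r{i}"], [], [f"p{i}"],
                         Arrow((70, 120 + 400 * i), (290, 120 + 400 * i)))
        )
    return ReactionScheme(600, 400 * k + 400, comps, steps, "multiple_line")


class TestMatchReactions:
    def test_identity_gives_perfect_scores(self):
        gt = k_step_scheme(3)
        r = match_reactions(
            [(s, gt) for s in gt.steps], [(s, gt) for s in gt.steps], "hard"
        )
        assert (r.precision, r.recall, r.f1) == (1.0, 1.0, 1.0)

    def test_hand_computed_partial_match(self):
        # 3 gt steps, 2 predictions of which exactly 1 matches:
        # P = 1/2, R = 1/3, F1 = 2*(1/2)*(1/3)/(1/2+1/3) = 0.4
        gt = k_step_scheme(3)
        pred = k_step_scheme(2, match_mask=[True, False])
        r = match_reactions(
            [(s, pred) for s in pred.steps], [(s, gt) for s in gt.steps], "hard"
        )
        assert r.tp == 1 and r.fp == 1 and r.fn == 2
        assert r.precision == pytest.approx(0.5)
        assert r.recall == pytest.approx(1 / 3)
        assert r.f1 == pytest.approx(0.4)

    def test_empty_predictions_score_zero(self):
        gt = k_step_scheme(2)
        r = match_reactions([], [(s, gt) for s in gt.steps], "hard")
        assert (r.precision, r.recall, r.f1) == (0.0, 0.0, 0.0)

    def test_order_invariance(self):
        gt = k_step_scheme(4)
        pred = k_step_scheme(4, match_mask=[True, False, True, True])
        base = match_reactions(
            [(s, pred) for s in pred.steps], [(s, gt) for s in gt.steps], "hard"
        )
        for perm in itertools.islice(itertools.permutations(range(4)), 8):
            r = match_reactions(
                [(pred.steps[i], pred) for i in perm],
                [(s, gt) for s in gt.steps], "hard",
            )
            assert (r.tp, r.fp, r.fn) == (base.tp, base.fp, base.fn)

    def test_matching_equals_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            n, m = int(rng.integers(0, 5)), int(rng.integers(0, 5))
            adj = rng.random((n, m)) < 0.4
            got = len(max_bipartite_matching([list(row) for row in adj]))
            best = 0
            for k in range(min(n, m), -1, -1):
                if best:
                    break
                for rows in itertools.permutations(range(n), k):
                    for cols in itertools.permutations(range(m), k):
                        if all(adj[r][c] for r, c in zip(rows, cols)):
                            best = k
                            break
                    if best:
                        break
            assert got == best


class TestByPattern:
    def test_single_pattern_equals_overall(self):
        gt = {f"img{i}": k_step_scheme(2) for i in range(3)}
        patterns = {k: "single_line" for k in gt}
        out = evaluate_by_pattern(gt, gt, patterns, "hard")
        assert out["single_line"].as_dict() == {
            **out["overall"].as_dict()}

    def test_pooled_counts_are_sums(self):
        gt = {"a": k_step_scheme(2), "b": k_step_scheme(3)}
        preds = {"a": k_step_scheme(2), "b": k_step_scheme(3, [True, False, False])}
        patterns = {"a": "single_line", "b": "branch"}
        out = evaluate_by_pattern(preds, gt, patterns, "hard")
        assert out["overall"].tp == out["single_line"].tp + out["branch"].tp
        assert out["overall"].fn == out["single_line"].fn + out["branch"].fn
        assert out["single_line"].f1 == 1.0 and out["branch"].f1 < 1.0

    def test_unknown_pattern_tag_is_hard_error(self):
        gt = {"a": k_step_scheme(1)}
        with pytest.raises(ValueError, match="zigzag"):
            evaluate_by_pattern(gt, gt, {"a": "zigzag"}, "hard")


def items_at(specs):
    out = []
    for i, (text, role) in enumerate(specs):
        box = BBox(10, 30 * i, 80, 30 * i + 20)
        out.append(ConditionItem(text, role, box))
    return out


class TestCRI:
    def test_all_correct_is_diagonal(self):
        gt = items_at([("H2", "agent"), ("THF", "solvent"), ("80 °C", "temperature"),
                       ("2 h", "time"), ("91%", "yield")])
        cm = evaluate_cri(gt, gt)
        assert cm.accuracy == 1.0
        for role in ("agent", "solvent", "temperature", "time", "yield"):
            assert cm.counts[role][role] == 1

    def test_one_solvent_predicted_agent(self):
        gt = items_at([("H2", "agent"), ("THF", "solvent"), ("80 °C", "temperature"),
                       ("2 h", "time"), ("91%", "yield")])
        pred = [
            it if it.role != "solvent" else ConditionItem(it.text, "agent", it.bbox)
            for it in gt
        ]
        cm = evaluate_cri(pred, gt)
        assert cm.accuracy == pytest.approx(0.8)
        assert cm.counts["solvent"]["agent"] == 1

    def test_unpaired_gt_goes_to_missed_column(self):
        gt = items_at([("THF", "solvent"), ("2 h", "time")])
        cm = evaluate_cri(gt[:1], gt)
        assert cm.counts["time"]["missed"] == 1
        assert cm.accuracy == pytest.approx(0.5)

    def test_per_role_scores(self):
        gt = items_at([("THF", "solvent"), ("DMF", "solvent")])
        pred = [gt[0], ConditionItem("DMF", "agent", gt[1].bbox)]
        scores = evaluate_cri(pred, gt).per_role()
        assert scores["solvent"]["recall"] == pytest.approx(0.5)
        assert scores["solvent"]["precision"] == pytest.approx(1.0)
        assert scores["agent"]["precision"] == pytest.approx(0.0)


class TestOCR:
    def test_degree_normalization(self):
        assert normalize_text("35 °C") == normalize_text("35C")
        assert normalize_text("35℃") == normalize_text("35 °C")

    def test_accuracy_counts(self):
        gt = items_at([("35 °C", "temperature"), ("THF", "solvent")])
        pred = [ConditionItem("35C", "temperature", gt[0].bbox),
                ConditionItem("DMF", "solvent", gt[1].bbox)]
        assert ocr_accuracy(pred, gt) == pytest.approx(0.5)
        assert ocr_accuracy(gt, gt) == 1.0


class TestSmilesAccuracy:
    def test_identity_and_half_wrong(self):
        gt = [["CCO>>CC=O"], ["CCO.CCBr>>CCOCC"]]
        assert smiles_exact_match_accuracy(gt, gt) == 1.0
        pred = [["CCO>>CC=O"], ["CCO.CCBr>>CCO"]]
        assert smiles_exact_match_accuracy(pred, gt) == pytest.approx(0.5)

    def test_non_canonical_equivalent_matches(self):
        gt = [["CCO>>CC=O"]]
        pred = [["OCC>>O=CC"]]
        assert smiles_exact_match_accuracy(pred, gt) == 1.0

    def test_unparseable_prediction_is_non_match(self):
        gt = [["CCO>>CC=O"]]
        assert smiles_exact_match_accuracy([["garbage"]], gt) == 0.0

    def test_step_order_insensitive(self):
        gt = [["CCO>>CC=O", "CCBr>>CCN"]]
        pred = [["CCBr>>CCN", "CCO>>CC=O"]]
        assert smiles_exact_match_accuracy(pred, gt) == 1.0
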