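"""Layout geometry and rendering invariants."""

import io
import itertools

import pytest

from rxnforge.conditions import ConditionSpec, sample_conditions
from rxnforge.layout import LayoutError, LayoutStep, layout_scheme
from rxnforge.reactions import parse_reaction_smiles
from rxnforge.render import render_scheme
from rxnforge.rng import RNGStream
from rxnforge.scheme import validate_scheme
from rxnforge.style import BUNDLED_FONTS, StyleConfig, StyleDraw

from rxnforge.conditions import _SENTINEL, ConditionItem


def mk_draw(pattern="single_line", font_size=14, line_width=2, scale=1.0):
    return StyleDraw(font_size, line_width, scale, pattern, BUNDLED_FONTS[0])


def mk_step(rxn, items):
    return LayoutStep(parse_reaction_smiles(rxn), items)


class TestPlacementRules:
    def test_agent_above_solvent_below_arrow(self, depictor, style):
        items = [
            ConditionItem("ArCHO", "agent", _SENTINEL),
            ConditionItem("THF", "solvent", _SENTINEL),
        ]
        s = layout_scheme(
            [mk_step("CCO.CCBr>>CCOCC", items)], "single_line", style, mk_draw(), depictor
        )
        step = s.steps[0]
        arrow_y = step.arrow.midpoint[1]
        placed = s.component(step.condition_ids[0]).items
        agent = next(i for i in placed if i.role == "agent")
        solvent = next(i for i in placed if i.role == "solvent")
        assert agent.bbox.center[1] < arrow_y
        assert solvent.bbox.center[1] > arrow_y

    def test_every_pattern_places_agents_above_others_below(self, scheme_pool):
        for gen in scheme_pool:
            for step in gen.scheme.steps:
                arrow_y = step.arrow.midpoint[1]
                for cid in step.condition_ids:
                    for item in gen.scheme.component(cid).items:
                        if item.role == "agent":
                            assert item.bbox.center[1] < arrow_y
                        else:
                            assert item.bbox.center[1] > arrow_y

    def test_overflow_wraps_to_continuation_line(self, depictor):
        style = StyleConfig(canvas_max_width=420)
        s = layout_scheme(
            [mk_step("Brc1ccccc1.OB(O)c1ccccc1>>c1ccc(-c2ccccc2)cc1", [])],
            "single_line", style, mk_draw(), depictor,
        )
        assert s.canvas_width <= 420
        assert validate_scheme(s) == []
        mols = s.molecule_components()
        rows = {round(m.bbox.center[1]) for m in mols}
        assert len(rows) > 1  # the product moved to a lower line
        product = s.component(s.steps[0].product_ids[0])
        assert product.bbox.center[1] > max(
            s.component(c).bbox.center[1] for c in s.steps[0].reactant_ids
        )

    def test_molecule_too_wide_for_canvas_errors(self, depictor):
        style = StyleConfig(canvas_max_width=200)
        with pytest.raises(LayoutError, match="canvas_max_width"):
            layout_scheme(
                [mk_step("CCCCCCCCCCCCCCCCCCCCCCCCCCCCCC>>CC", [])],
                "single_line", style, mk_draw(scale=1.3), depictor,
            )

    def test_cycle_forms_closed_arrow_chain(self, depictor, style):
        nodes = ["CCO", "CC=O", "CC(=O)O", "CC(=O)OC"]
        steps = [
            mk_step(f"{nodes[i]}>>{nodes[(i + 1) % 4]}", []) for i in range(4)
        ]
        s = layout_scheme(steps, "cycle", style, mk_draw("cycle"), depictor)
        assert validate_scheme(s) == []
        assert len(s.steps) == 4
        # consecutive pairs joined; the last arrow returns to the first component
        for i in range(4):
            assert s.steps[i].product_ids == s.steps[(i + 1) % 4].reactant_ids
        assert s.steps[3].product_ids == s.steps[0].reactant_ids
        # centroids lie on one closed loop around the common center
        import math
        cx = sum(c.bbox.center[0] for c in s.molecule_components()) / 4
        cy = sum(c.bbox.center[1] for c in s.molecule_components()) / 4
        radii = [
            math.hypot(c.bbox.center[0] - cx, c.bbox.center[1] - cy)
            for c in s.molecule_components()
        ]
        # centers move by <1 px when boxes are rounded to integer pixels
        assert max(radii) - min(radii) <= 1.0

    def test_branch_shares_reactant_across_arms(self, depictor, style, toy_source):
        group = [parse_reaction_smiles(r) for r in toy_source.draw_group(RNGStream(1), 3)]
        steps = [LayoutStep(r, []) for r in group]
        s = layout_scheme(steps, "branch", style, mk_draw("branch"), depictor)
        assert validate_scheme(s) == []
        roots = {tuple(st.reactant_ids) for st in s.steps}
        assert len(roots) == 1  # one shared reactant set, >=2 outgoing arrows
        assert len(s.steps) >= 2

    def test_molecule_boxes_never_overlap(self, scheme_pool):
        for gen in scheme_pool:
            mols = gen.scheme.molecule_components()
            for a, b in itertools.combinations(mols, 2):
                assert a.bbox.iou(b.bbox) == 0.0


class TestRender:
    def test_finalized_boxes_positive_and_inside_canvas(self, scheme_pool, depictor):
        for gen in scheme_pool[:6]:
            _, final = render_scheme(gen.scheme, gen.draw, depictor)
            assert validate_scheme(final) == []
            for c in final.components:
                assert c.bbox.area > 0
                assert 0 <= c.bbox.x_min < c.bbox.x_max <= final.canvas_width
                assert 0 <= c.bbox.y_min < c.bbox.y_max <= final.canvas_height

    def test_same_inputs_render_identically(self, scheme_pool, depictor):
        gen = scheme_pool[0]
        img1, fin1 = render_scheme(gen.scheme, gen.draw, depictor)
        img2, fin2 = render_scheme(gen.scheme, gen.draw, depictor)
        b1, b2 = io.BytesIO(), io.BytesIO()
        img1.save(b1, "PNG")
        img2.save(b2, "PNG")
        assert b1.getvalue() == b2.getvalue()
        assert fin1 == fin2

    @pytest.mark.parametrize("font_size,line_width,scale", [(11, 1, 0.8), (18, 3, 1.3)])
    def test_style_range_extremes_render_and_validate(
        self, depictor, style, font_size, line_width, scale
    ):
        items = sample_conditions(RNGStream(9), ConditionSpec())
        s = layout_scheme(
            [mk_step("CCO.CC(=O)O>[H+]>CCOC(C)=O", items)],
            "single_line", style,
            mk_draw(font_size=font_size, line_width=line_width, scale=scale),
            depictor,
        )
        _, final = render_scheme(
            s, mk_draw(font_size=font_size, line_width=line_width, scale=scale), depictor
        )
        assert validate_scheme(final) == []

    def test_rotated_condition_text_keeps_valid_boxes(self, depictor, style):
        draw = StyleDraw(14, 2, 1.0, "single_line", BUNDLED_FONTS[0], rotation=25.0)
        items = [ConditionItem("R1 = Ar, Alk", "other", _SENTINEL)]
        s = layout_scheme([mk_step("CCO>>CC=O", items)], "single_line", style, draw, depictor)
        _, final = render_scheme(s, draw, depictor)
        assert validate_scheme(final) == []
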