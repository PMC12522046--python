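"""Domain model: validation, reaction SMILES assembly/equality, arrow semantics."""

import itertools

import pytest
from rdkit import Chem

from rxnforge.scheme import (
    Arrow,
    BBox,
    Component,
    ConditionItem,
    ReactionParseError,
    ReactionScheme,
    ReactionStep,
    SchemeError,
    assemble_reaction_smiles,
    expand_bidirectional,
    reaction_equal,
    validate_scheme,
)


def _mol(cid, role, box, smiles):
    return Component(cid, role, box, smiles=smiles)


def simple_scheme(products=("CC=O",), arrow_kind="straight", crossed=False):
    comps = [
        _mol("r0", "reactant", BBox(10, 10, 60, 60), "CCO"),
        *[
            _mol(f"p{i}", "product", BBox(200 + 70 * i, 10, 260 + 70 * i, 60), smi)
            for i, smi in enumerate(products)
        ],
    ]
    step = ReactionStep(
        ["r0"], [], [f"p{i}" for i in range(len(products))],
        Arrow((70, 35), (190, 35), arrow_kind, crossed),
    )
    return ReactionScheme(500, 100, comps, [step], "single_line")


class TestValidation:
    def test_well_formed_scheme_has_no_violations(self):
        assert validate_scheme(simple_scheme()) == []

    def test_step_without_product_is_flagged(self):
        s = simple_scheme()
        s.steps[0].product_ids = []
        rules = {v.rule for v in validate_scheme(s)}
        assert "step missing product" in rules

    def test_bbox_outside_canvas_is_flagged(self):
        s = simple_scheme()
        s.components[0].bbox = BBox(10, 10, 600, 60)  # x_max > canvas_width
        rules = {v.rule for v in validate_scheme(s)}
        assert "bbox outside canvas" in rules

    def test_condition_payload_and_bad_smiles_flagged(self):
        s = simple_scheme()
        s.components.append(Component("c0", "condition", BBox(80, 70, 120, 90), items=[]))
        s.steps[0].condition_ids = ["c0"]
        assert validate_scheme(s) == []
        s.components[0].smiles = "not-a-smiles"
        assert any(v.rule == "invalid SMILES" for v in validate_scheme(s))


class TestAssembly:
    def test_empty_agent_field(self):
        s = simple_scheme()
        assert assemble_reaction_smiles(s.steps[0], s) == "CCO>>CC=O"

    def test_agents_and_multiple_reactants(self):
        comps = [
            _mol("r0", "reactant", BBox(0, 0, 40, 40), "CCO"),
            _mol("r1", "reactant", BBox(50, 0, 90, 40), "CC(=O)O"),
            Component(
                "c0", "condition", BBox(100, 0, 130, 20),
                items=[ConditionItem("[H+]", "agent", BBox(100, 0, 130, 20))],
            ),
            _mol("p0", "product", BBox(200, 0, 240, 40), "CCOC(C)=O"),
        ]
        step = ReactionStep(["r0", "r1"], ["c0"], ["p0"], Arrow((95, 20), (195, 20)))
        scheme = ReactionScheme(300, 50, comps, [step], "single_line")
        assert assemble_reaction_smiles(step, scheme) == "CCO.CC(=O)O>[H+]>CCOC(C)=O"

    def test_name_agents_stay_out_of_smiles(self):
        comps = [
            _mol("r0", "reactant", BBox(0, 0, 40, 40), "CCO"),
            Component(
                "c0", "condition", BBox(100, 0, 130, 20),
                items=[ConditionItem("Pd/C", "agent", BBox(100, 0, 130, 20))],
            ),
            _mol("p0", "product", BBox(200, 0, 240, 40), "CC=O"),
        ]
        step = ReactionStep(["r0"], ["c0"], ["p0"], Arrow((50, 20), (195, 20)))
        scheme = ReactionScheme(300, 50, comps, [step], "single_line")
        assert assemble_reaction_smiles(step, scheme) == "CCO>>CC=O"

    def test_dangling_product_id_is_hard_error(self):
        s = simple_scheme()
        s.steps[0].product_ids = ["ghost"]
        with pytest.raises(SchemeError, match="ghost"):
            assemble_reaction_smiles(s.steps[0], s)

    def test_assembled_output_reparses_and_is_self_equal(self, scheme_pool):
        for gen in scheme_pool[:20]:
            for step in gen.scheme.steps:
                asm = assemble_reaction_smiles(step, gen.scheme)
                assert reaction_equal(asm, asm)


def _independent_equal(a: str, b: str) -> bool:
    """Canonicalize-sort-compare oracle built directly on RDKit."""
    def key(rxn):
        fields = rxn.split(">")
        return [sorted(Chem.CanonSmiles(m) for m in f.split(".") if m) for f in fields]

    return key(a) == key(b)


EQUIV_PAIRS = [
    ("CCO>>CC=O", "CCO>>CC=O", True),
    ("OCC>>O=CC", "CCO>>CC=O", True),
    ("CCO.CCBr>>CC=O", "CCBr.CCO>>CC=O", True),
    ("CCO>[H+]>CC=O", "OCC>[H+]>CC=O", True),
    ("CCO>>CC=O", "CCO>>CCO", False),
    ("CCO>O>CC=O", "CCO>>CC=O", False),
    ("c1ccccc1>>Brc1ccccc1", "C1=CC=CC=C1>>BrC1=CC=CC=C1", True),
]


class TestReactionEqual:
    @pytest.mark.parametrize("a,b,expected", EQUIV_PAIRS)
    def test_matches_independent_oracle(self, a, b, expected):
        assert reaction_equal(a, b) is expected
        assert _independent_equal(a, b) is expected

    def test_agent_field_flag(self):
        assert reaction_equal("CCO>O>CC=O", "CCO>>CC=O", compare_agents=False)
        assert not reaction_equal("CCO>O>CC=O", "CCO>>CC=O", compare_agents=True)

    def test_unparseable_side_is_named(self):
        with pytest.raises(ReactionParseError, match="left"):
            reaction_equal("xx>>CC", "CCO>>CC=O")
        with pytest.raises(ReactionParseError, match="right"):
            reaction_equal("CCO>>CC=O", "xx>>CC")

    def test_equivalence_relation_on_fixture_set(self):
        fixtures = [
            "CCO>>CC=O", "OCC>>O=CC", "CCO.CCBr>>CC=O", "CCBr.CCO>>CC=O",
            "c1ccccc1>>Brc1ccccc1", "C1=CC=CC=C1>>BrC1=CC=CC=C1",
        ]
        for a in fixtures:
            assert reaction_equal(a, a)  # reflexive
        for a, b in itertools.permutations(fixtures, 2):
            assert reaction_equal(a, b) == reaction_equal(b, a)  # symmetric
        for a, b, c in itertools.permutations(fixtures, 3):  # transitive
            if reaction_equal(a, b) and reaction_equal(b, c):
                assert reaction_equal(a, c)


class TestExpandBidirectional:
    def test_equilibrium_becomes_two_directions(self):
        s = simple_scheme(arrow_kind="bidirectional")
        out = expand_bidirectional(s)
        assert len(out.steps) == 2
        fwd, rev = out.steps
        assert fwd.reactant_ids == ["r0"] and fwd.product_ids == ["p0"]
        assert rev.reactant_ids == ["p0"] and rev.product_ids == ["r0"]
        assert {st.arrow.kind for st in out.steps} == {"straight"}

    def test_straight_arrows_unchanged(self):
        s = simple_scheme()
        out = expand_bidirectional(s)
        assert len(out.steps) == 1
        assert out.steps[0].reactant_ids == s.steps[0].reactant_ids

    def test_crossed_out_step_dropped(self):
        s = simple_scheme(crossed=True)
        assert expand_bidirectional(s).steps == []

    def test_idempotent(self):
        s = simple_scheme(arrow_kind="bidirectional")
        once = expand_bidirectional(s)
        twice = expand_bidirectional(once)
        assert [st.reactant_ids for st in twice.steps] == [st.reactant_ids for st in once.steps]
        assert [st.arrow.kind for st in twice.steps] == [st.arrow.kind for st in once.steps]
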