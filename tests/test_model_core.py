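"""Model types, GPR parsing/evaluation and model IO."""

import itertools
import json

import pytest
from hypothesis import given, settings, strategies as st

from fluxscreen.model_core import (
    EMPTY_GPR,
    GprParseError,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    evaluate_gpr,
    inactivate_for_genes,
    parse_gpr,
    read_model,
    render_gpr,
    write_model,
)

from conftest import eval_rule_text, make_model, make_reaction


class TestParseGpr:
    @pytest.mark.parametrize(
        "text,kind,n_children",
        [
            ("g1 or g2", "OR", 2),
            ("(g1 and g2) or g3", "OR", 2),
            ("g1 and g2 and g3", "AND", 3),  # associative chain flattened
            ("g1 or g2 or g3 or g4", "OR", 4),
            ("g1 || g2", "OR", 2),
            ("g1 && g2", "AND", 2),
            ("G1 AND g2", "AND", 2),  # case-insensitive operators
        ],
    )
    def test_structure(self, text, kind, n_children):
        expr = parse_gpr(text)
        assert expr.kind == kind
        assert len(expr.children) == n_children

    def test_single_gene_and_empty(self):
        assert parse_gpr("g1").kind == "GENE"
        assert parse_gpr("").is_empty()
        assert parse_gpr("   ").is_empty()
        assert parse_gpr(None).is_empty()

    def test_nested_precedence(self):
        expr = parse_gpr("(g1 and g2) or g3")
        assert expr.kind == "OR"
        assert {c.kind for c in expr.children} == {"AND", "GENE"}

    @pytest.mark.parametrize("bad", ["g1 or", "(g1 and g2", "and g1", "g1 )", "or"])
    def test_parse_errors(self, bad):
        with pytest.raises(GprParseError):
            parse_gpr(bad)

    @pytest.mark.parametrize(
        "rule,genes",
        [
            ("g1 and (g2 or (g3 and g4))", ["g1", "g2", "g3", "g4"]),
            ("(g1 or g2) and (g3 or g4)", ["g1", "g2", "g3", "g4"]),
            ("g1 or (g2 and g3)", ["g1", "g2", "g3"]),
        ],
    )
    def test_truth_table_matches_eval_oracle(self, rule, genes):
        """Parsed evaluation agrees with direct boolean eval of the rule text
        over every gene-state assignment."""
        expr = parse_gpr(rule)
        for states in itertools.product([False, True], repeat=len(genes)):
            inactive = {g for g, alive in zip(genes, states) if not alive}
            assert evaluate_gpr(expr, inactive) == eval_rule_text(rule, inactive)


# Random normalized GPR trees for the round-trip property.
gene_ids = st.sampled_from([f"g{i}" for i in range(1, 7)])


def gpr_trees():
    return st.recursive(
        gene_ids.map(lambda g: parse_gpr(g)),
        lambda children: st.tuples(
            st.sampled_from(["and", "or"]),
            st.lists(children, min_size=2, max_size=3),
        ).map(lambda t: parse_gpr(f" {t[0]} ".join(f"({render_gpr(c)})" for c in t[1]))),
        max_leaves=8,
    )


class TestGprProperties:
    @given(gpr_trees())
    @settings(max_examples=100, deadline=None)
    def test_render_parse_roundtrip(self, expr):
        assert parse_gpr(render_gpr(expr)) == expr

    @given(gpr_trees(), st.sets(gene_ids), st.sets(gene_ids))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_inactive_set(self, expr, a, b):
        """Enlarging the knockout set never reactivates an expression."""
        if not evaluate_gpr(expr, a):
            assert not evaluate_gpr(expr, a | b)

    @given(gpr_trees())
    @settings(max_examples=50, deadline=None)
    def test_empty_knockout_is_true(self, expr):
        assert evaluate_gpr(expr, set())

    @given(gpr_trees())
    @settings(max_examples=30, deadline=None)
    def test_agrees_with_cobra_rule_evaluation(self, expr):
        """Cross-check evaluation against cobrapy's GPR engine."""
        from cobra.core.gene import GPR

        rule = render_gpr(expr)
        cobra_gpr = GPR.from_string(rule)
        for inactive in ({"g1"}, {"g2", "g3"}, set(expr.genes())):
            assert evaluate_gpr(expr, inactive) == cobra_gpr.eval(knockouts=inactive)


class TestEvaluateGpr:
    def test_isozyme_survives_single_knockout(self):
        assert evaluate_gpr(parse_gpr("g1 or g2"), {"g1"}) is True

    def test_complex_requires_all_subunits(self):
        assert evaluate_gpr(parse_gpr("g1 and g2"), {"g1"}) is False

    def test_nested(self):
        assert evaluate_gpr(parse_gpr("(g1 and g2) or g3"), {"g1", "g3"}) is False

    def test_empty_gpr_always_true(self):
        assert evaluate_gpr(EMPTY_GPR, {"g1", "g2"}) is True


class TestInactivateForGenes:
    def test_shuts_exactly_dependent_reactions(self, isozyme_model):
        model = make_model(
            "m", ["A", "B"],
            [
                make_reaction("EX_A", {"A": -1}, lb=-10.0),
                make_reaction("R1", {"A": -1, "B": 1}, gpr="g1 or g2"),
                make_reaction("R2", {"B": -1}, gpr="g1"),
            ],
        )
        assert inactivate_for_genes(model, {"g1"}) == {"R2"}
        assert inactivate_for_genes(model, set()) == set()
        assert inactivate_for_genes(model, {"g1", "g2"}) == {"R1", "R2"}
        assert inactivate_for_genes(model, {"not_a_gene"}) == set()

    def test_matches_per_reaction_truth_table(self, two_path_model):
        """Single-gene partition equals the rule-text eval oracle per reaction."""
        for gene in two_path_model.genes:
            expected = {
                r.reaction_id
                for r in two_path_model.reactions
                if render_gpr(r.gpr) and not eval_rule_text(render_gpr(r.gpr), {gene})
            }
            assert inactivate_for_genes(two_path_model, {gene}) == expected


class TestModelValidation:
    def test_bounds_inverted_rejected(self):
        with pytest.raises(ModelValidationError, match="lower bound"):
            make_model("bad", ["A"], [make_reaction("R", {"A": -1}, lb=5.0, ub=3.0)])

    def test_undeclared_metabolite_rejected(self):
        with pytest.raises(ModelValidationError, match="undeclared metabolites"):
            MetabolicModel(
                model_id="bad",
                metabolites=[Metabolite("A")],
                reactions=[make_reaction("R", {"A": -1, "B": 1})],
            )

    def test_gpr_gene_must_be_declared(self):
        with pytest.raises(ModelValidationError, match="undeclared genes"):
            MetabolicModel(
                model_id="bad",
                metabolites=[Metabolite("A")],
                reactions=[make_reaction("R", {"A": -1}, gpr="g1")],
                genes=[],
            )

    def test_objective_must_exist(self):
        with pytest.raises(ModelValidationError, match="biomass"):
            MetabolicModel(
                model_id="bad",
                metabolites=[Metabolite("A")],
                reactions=[make_reaction("R", {"A": -1})],
                biomass_reaction="NOPE",
            )


class TestModelIO:
    def test_json_fixture_parses(self, tmp_path):
        data = {
            "model_id": "toy",
            "metabolites": ["A", "B"],
            "reactions": [
                {"id": "R1", "stoich": {"A": -1, "B": 1}, "lb": 0, "ub": 10, "gpr": "g1 or g2"},
                {"id": "EX_A", "stoich": {"A": -1}, "lb": -10, "ub": 10},
                {"id": "EX_B", "stoich": {"B": -1}, "lb": 0, "ub": 10},
            ],
        }
        path = tmp_path / "toy.json"
        path.write_text(json.dumps(data))
        model = read_model(path)
        assert len(model.reactions) == 3
        assert model.genes == ["g1", "g2"]
        assert model.exchange_reactions == {"EX_A", "EX_B"}

    def test_json_roundtrip(self, tmp_path, two_path_model):
        path = tmp_path / "m.json"
        write_model(two_path_model, path)
        back = read_model(path)
        assert back.model_id == two_path_model.model_id
        assert back.reaction_ids == two_path_model.reaction_ids
        assert back.genes == two_path_model.genes
        assert back.biomass_reaction == "BIOMASS"
        for r1, r2 in zip(two_path_model.reactions, back.reactions):
            assert r1 == r2

    def test_sbml_roundtrip(self, tmp_path, two_path_model):
        path = tmp_path / "m.xml"
        write_model(two_path_model, path, format="sbml")
        back = read_model(path, format="sbml")
        assert set(back.reaction_ids) == set(two_path_model.reaction_ids)
        assert set(back.genes) == set(two_path_model.genes)
        assert back.biomass_reaction == "BIOMASS"
        for rid in two_path_model.reaction_ids:
            r1, r2 = two_path_model.reaction(rid), back.reaction(rid)
            assert r1.stoichiometry == r2.stoichiometry
            assert r1.lower_bound == r2.lower_bound
            assert r1.upper_bound == r2.upper_bound
            assert render_gpr(r1.gpr) == render_gpr(r2.gpr)

    def test_sbml_readable_by_cobra(self, tmp_path, isozyme_model):
        """The SBML we emit is valid FBC for an independent reader."""
        import cobra.io

        path = tmp_path / "m.xml"
        write_model(isozyme_model, path, format="sbml")
        # f_replace={} keeps raw ids (no COBRA R_/M_ prefix stripping)
        cm = cobra.io.read_sbml_model(str(path), f_replace={})
        assert {r.id for r in cm.reactions} == set(isozyme_model.reaction_ids)
        assert cm.slim_optimize() == pytest.approx(10.0)

    def test_malformed_json_raises(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(ModelValidationError, match="malformed"):
            read_model(path)
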