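"""Discretization, core derivation, FASTCORE extraction and model building."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fluxscreen.context import (
    EXPRESSED,
    NOT_EXPRESSED,
    UNKNOWN,
    BlockedCoreError,
    build_consensus_model,
    build_sample_models,
    consensus_core,
    discretize_expression,
    fastcore,
    fastcore_extract,
    reaction_core_from_calls,
    reactions_off_from_calls,
)
from fluxscreen.fba import DEFAULT_EPSILON, Medium, fastcc
from fluxscreen.synthetic import SyntheticSpec, generate_expression, generate_network

from conftest import consistent_reactions_oracle, make_model, make_reaction


# ---------------------------------------------------------------------------
# Exhaustive oracle for near-minimality
# ---------------------------------------------------------------------------

def min_consistent_superset_size(model, core, epsilon=DEFAULT_EPSILON):
    """Cardinality of the smallest self-consistent reaction set containing
    the core, by exhaustive subset search (per-reaction LP consistency)."""
    core = set(core)
    non_core = sorted(set(model.reaction_ids) - core)
    for k in range(len(non_core) + 1):
        for extra in itertools.combinations(non_core, k):
            candidate = core | set(extra)
            sub = model.subset(candidate)
            if consistent_reactions_oracle(sub, epsilon) == candidate:
                return len(candidate)
    raise AssertionError("no consistent superset exists")


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

class TestDiscretize:
    def test_bimodal_sample_recovers_modes_without_hard_flips(self):
        """500 genes from log2 modes at -5 and +5 (sd 1): no expressed gene is
        called not-expressed and vice versa; unknowns lie only between the
        component means."""
        rng = np.random.default_rng(7)
        labels = np.array([True] * 250 + [False] * 250)
        values = np.exp2(rng.normal(np.where(labels, 5.0, -5.0), 1.0))
        matrix = pd.DataFrame({"s1": values}, index=[f"g{i}" for i in range(500)])
        calls = discretize_expression(matrix)["s1"].values
        assert not ((calls == NOT_EXPRESSED) & labels).any()
        assert not ((calls == EXPRESSED) & ~labels).any()
        # both decisive zones are populated
        assert (calls[labels] == EXPRESSED).sum() > 100
        assert (calls[~labels] == NOT_EXPRESSED).sum() > 100

    def test_all_zero_gene_not_expressed_everywhere(self):
        rng = np.random.default_rng(1)
        matrix = pd.DataFrame(
            np.exp2(rng.normal([[5.0]] * 30 + [[-5.0]] * 30, 1.0, (60, 3))),
            columns=["a", "b", "c"],
        )
        matrix.iloc[0] = 0.0
        calls = discretize_expression(matrix)
        assert (calls.iloc[0] == NOT_EXPRESSED).all()

    def test_point_mass_clusters_boundary_inclusive_upward(self):
        """With two tight clusters the fitted upper mean sits at the cluster
        value; genes exactly at that value are called expressed."""
        low, high = 2.0**1 - 1, 2.0**8 - 1  # log2(x+1) exactly 1 and 8
        matrix = pd.DataFrame(
            {"s": [low] * 50 + [high] * 50},
            index=[f"g{i}" for i in range(100)],
        )
        calls = discretize_expression(matrix)["s"]
        assert (calls.iloc[50:] == EXPRESSED).all()
        assert (calls.iloc[:50] == NOT_EXPRESSED).all()

    def test_unimodal_sample_falls_back_to_percentile_cut(self):
        rng = np.random.default_rng(3)
        matrix = pd.DataFrame(
            {"s": np.exp2(rng.normal(3.0, 0.1, 200))},
            index=[f"g{i}" for i in range(200)],
        )
        with pytest.warns(UserWarning, match="unimodal"):
            calls = discretize_expression(matrix)["s"]
        assert set(calls.unique()) <= {EXPRESSED, NOT_EXPRESSED}
        assert 0 < (calls == EXPRESSED).sum() < 200

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            discretize_expression(pd.DataFrame({"s": [-1.0, 2.0]}))

    def test_mode_swap_inverts_decisive_calls(self):
        """Swapping which genes sit in the expressed mode inverts the calls."""
        spec = SyntheticSpec(n_samples_cancer=2, n_samples_control=1)
        model = generate_network(spec)
        matrix, truth = generate_expression(spec, model)
        calls = discretize_expression(matrix)
        swapped_spec = SyntheticSpec(
            n_samples_cancer=2, n_samples_control=1,
            expressed_log2_mean=-5.0, silent_log2_mean=5.0,
        )
        # same draw geometry with modes exchanged: truth-expressed genes now
        # sit in the low mode and must never be called expressed
        matrix2, truth2 = generate_expression(swapped_spec, model)
        calls2 = discretize_expression(matrix2)
        decisive = (calls.values != UNKNOWN) & (calls2.values != UNKNOWN)
        assert (calls.values[decisive] == -calls2.values[decisive]).all()

    def test_swapped_modes_spec_requires_wide_separation(self):
        with pytest.raises(ValueError, match="separated"):
            SyntheticSpec(expressed_log2_mean=1.0, silent_log2_mean=0.0)


# ---------------------------------------------------------------------------
# Core derivation
# ---------------------------------------------------------------------------

class TestReactionCore:
    @pytest.fixture
    def core_model(self):
        return make_model(
            "core", ["A", "B", "C"],
            [
                make_reaction("R1", {"A": -1, "B": 1}, gpr="g1 or g2"),
                make_reaction("R2", {"B": -1, "C": 1}, gpr="g1 and g2"),
                make_reaction("T", {"C": -1, "A": 1}),  # no GPR: scaffold
            ],
        )

    def calls(self, **genes):
        return pd.DataFrame({"s": pd.Series(genes)})

    def test_isozyme_core_with_one_expressed(self, core_model):
        calls = self.calls(g1=EXPRESSED, g2=NOT_EXPRESSED)
        assert "R1" in reaction_core_from_calls(core_model, calls, "s")

    def test_complex_not_core_with_one_missing(self, core_model):
        calls = self.calls(g1=EXPRESSED, g2=NOT_EXPRESSED)
        assert "R2" not in reaction_core_from_calls(core_model, calls, "s")

    def test_unknown_counts_as_off_for_core(self, core_model):
        calls = self.calls(g1=EXPRESSED, g2=UNKNOWN)
        assert reaction_core_from_calls(core_model, calls, "s") == {"R1"}

    def test_gpr_free_reaction_never_core(self, core_model):
        calls = self.calls(g1=EXPRESSED, g2=EXPRESSED)
        assert "T" not in reaction_core_from_calls(core_model, calls, "s")

    def test_off_requires_confident_silence(self, core_model):
        # unknown gene keeps the reaction available (not off), while a
        # confidently silent isozyme pair switches the reaction off
        calls = self.calls(g1=UNKNOWN, g2=NOT_EXPRESSED)
        assert reactions_off_from_calls(core_model, calls, "s") == {"R2"}
        calls = self.calls(g1=NOT_EXPRESSED, g2=NOT_EXPRESSED)
        assert reactions_off_from_calls(core_model, calls, "s") == {"R1", "R2"}

    def test_missing_sample_raises(self, core_model):
        with pytest.raises(KeyError):
            reaction_core_from_calls(core_model, self.calls(g1=1), "nope")


# ---------------------------------------------------------------------------
# FASTCORE
# ---------------------------------------------------------------------------

class TestFastcore:
    def test_prefers_short_path(self, two_path_model):
        kept = fastcore(two_path_model, {"BIOMASS"})
        assert kept == {"EX_A", "P_short", "BIOMASS"}

    def test_empty_core_gives_empty_model(self, two_path_model):
        assert fastcore(two_path_model, set()) == set()

    def test_full_core_is_identity_on_consistent_network(self, two_path_model):
        assert fastcore(two_path_model, set(two_path_model.reaction_ids)) == set(
            two_path_model.reaction_ids
        )

    def test_core_always_contained_in_output(self, two_path_model):
        for core in [{"P_long_2"}, {"P_long_1", "BIOMASS"}, {"P_short"}]:
            kept = fastcore(two_path_model, core)
            assert core <= kept

    def test_output_is_self_consistent(self, two_path_model):
        kept = fastcore(two_path_model, {"P_long_2"})
        sub = two_path_model.subset(kept)
        assert fastcc(sub, DEFAULT_EPSILON) == kept
        assert consistent_reactions_oracle(sub, DEFAULT_EPSILON) == kept

    def test_blocked_core_reaction_raises(self):
        model = make_model(
            "blocked", ["A", "D"],
            [
                make_reaction("EX_A", {"A": -1}, lb=-10.0),
                make_reaction("S_A", {"A": -1}),
                make_reaction("R_dead", {"A": -1, "D": 1}),
            ],
        )
        with pytest.raises(BlockedCoreError, match="R_dead"):
            fastcore(model, {"R_dead"})

    @pytest.mark.parametrize(
        "core",
        [{"BIOMASS"}, {"P_long_2"}, {"P_long_1", "P_long_3"}, {"P_short", "BIOMASS"}],
    )
    def test_near_minimal_on_two_path_network(self, two_path_model, core):
        kept = fastcore(two_path_model, core)
        assert len(kept) <= min_consistent_superset_size(two_path_model, core) + 1

    def test_near_minimal_with_reversible_core(self):
        model = make_model(
            "rev_core", ["A", "B", "C"],
            [
                make_reaction("EX_A", {"A": -1}, lb=-10.0),
                make_reaction("R1", {"A": -1, "B": 1}, lb=-1000.0),
                make_reaction("R2", {"B": -1, "C": 1}, lb=-1000.0),
                make_reaction("EX_C", {"C": -1}),
                make_reaction("Shortcut", {"A": -1, "C": 1}),
            ],
        )
        for core in [{"R1"}, {"R2"}, {"Shortcut"}]:
            kept = fastcore(model, core)
            assert core <= kept
            sub = model.subset(kept)
            assert consistent_reactions_oracle(sub, DEFAULT_EPSILON) == kept
            assert len(kept) <= min_consistent_superset_size(model, core) + 1


# ---------------------------------------------------------------------------
# Sample and consensus model building
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def synth_model():
    return generate_network(SyntheticSpec())


class TestBuildModels:
    def make_calls(self, model, columns):
        return pd.DataFrame(columns, index=model.genes).fillna(NOT_EXPRESSED).astype(int)

    def test_identical_calls_give_identical_models(self, synth_model):
        col = {g: EXPRESSED for g in synth_model.genes}
        calls = self.make_calls(synth_model, {f"s{i}": col for i in range(5)})
        contexts = build_sample_models(synth_model, calls, Medium({"glc_e": 10.0}), "cancer")
        assert len(contexts) == 5
        assert len({ctx.kept_reactions for ctx in contexts}) == 1
        assert all(ctx.viable for ctx in contexts)

    def test_silenced_biomass_route_flags_non_viable(self, synth_model):
        col = {g: EXPRESSED for g in synth_model.genes}
        col["g_c1"] = NOT_EXPRESSED  # only route to the biomass precursor
        calls = self.make_calls(synth_model, {"s0": col})
        ctx = build_sample_models(synth_model, calls, Medium({"glc_e": 10.0}), "cancer")[0]
        assert not ctx.viable
        assert ctx.kept_reactions == frozenset()

    def test_control_condition_forces_atp_maintenance(self, synth_model):
        col = {g: EXPRESSED for g in synth_model.genes}
        calls = self.make_calls(synth_model, {"s0": col})
        ctx = build_sample_models(synth_model, calls, Medium({"glc_e": 10.0}), "control")[0]
        assert ctx.objective_reaction == "ATPM"
        assert ctx.viable

    def test_build_is_deterministic(self, synth_model):
        spec = SyntheticSpec(n_samples_cancer=3, n_samples_control=0)
        matrix, _ = generate_expression(spec, synth_model)
        calls = discretize_expression(matrix)
        medium = Medium({"glc_e": 10.0})
        a = build_sample_models(synth_model, calls, medium, "cancer")
        b = build_sample_models(synth_model, calls, medium, "cancer")
        assert [c.kept_reactions for c in a] == [c.kept_reactions for c in b]

    def test_extracted_models_are_self_consistent_and_contain_core(self, synth_model):
        spec = SyntheticSpec(n_samples_cancer=3, n_samples_control=0)
        matrix, _ = generate_expression(spec, synth_model)
        calls = discretize_expression(matrix)
        contexts = build_sample_models(synth_model, calls, Medium({"glc_e": 10.0}), "cancer")
        for ctx in contexts:
            kept = set(ctx.kept_reactions)
            assert fastcc(ctx.model, DEFAULT_EPSILON) == kept
            assert "BIOMASS" in kept  # forced objective


class TestConsensus:
    def grid_calls(self, model, reaction_gene, n_on, n_total):
        """n_total samples; `reaction_gene` expressed in the first n_on."""
        cols = {}
        for i in range(n_total):
            col = {g: EXPRESSED for g in model.genes}
            if i >= n_on:
                col[reaction_gene] = NOT_EXPRESSED
            cols[f"s{i}"] = col
        return pd.DataFrame(cols, index=model.genes).astype(int)

    @pytest.mark.parametrize("n_on,expected", [(9, True), (10, True), (5, False)])
    def test_activity_fraction_boundary_inclusive(self, synth_model, n_on, expected):
        calls = self.grid_calls(synth_model, "g_c1", n_on, 10)
        core = consensus_core(synth_model, calls, activity_fraction=0.9)
        assert ("R_c1" in core) is expected

    def test_consensus_kept_subset_of_sample_union(self, synth_model):
        spec = SyntheticSpec(n_samples_cancer=6, n_samples_control=0)
        matrix, _ = generate_expression(spec, synth_model)
        calls = discretize_expression(matrix)
        medium = Medium({"glc_e": 10.0})
        samples = build_sample_models(synth_model, calls, medium, "cancer")
        consensus = build_consensus_model(synth_model, calls, medium, "cancer")
        union = set().union(*(c.kept_reactions for c in samples))
        assert set(consensus.kept_reactions) <= union

    def test_empty_calls_error(self, synth_model):
        calls = pd.DataFrame(index=synth_model.genes)
        with pytest.raises(ValueError):
            build_consensus_model(synth_model, calls, Medium({"glc_e": 10.0}), "cancer")
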