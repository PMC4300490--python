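"""Peptide filters, AP merging, network substitution, variants, ensemble."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from costim.core import CoStimDataset, LogicNetwork, NodeRole, StimulationDesign
from costim.network import (
    EnsembleScheme,
    VariantSpec,
    ap_merge,
    apply_variant,
    build_pepnet,
    cv_filter,
    enumerate_ensemble,
    load_ensemble_scheme,
    load_modeling_peptides,
    load_prior_network,
    missingness_filter,
)
from costim.preprocess import average_replicates
from costim.synthetic import ArchetypeSpec, BaseShape, NoiseModel, add_noise, generate_truth


def _replicate_dataset(values_by_cond, design):
    """values_by_cond: ppep -> condition -> replicate tuple."""
    rows = []
    for ppep, conds in values_by_cond.items():
        for (tn, tp), reps in conds.items():
            for r, v in enumerate(reps, start=1):
                rows.append((ppep, tn, tp, r, f"run{tn}_{tp}_{r}", v))
    df = pd.DataFrame(
        rows, columns=["ppep_id", "t_nacl", "t_phe", "replicate", "run_id", "intensity"]
    )
    df["protein"] = df["ppep_id"].str.split("_").str[0]
    df["sites"] = ""
    df["sequence"] = ""
    df["n_phospho"] = 1
    tic = df.groupby("run_id")["intensity"].sum(min_count=1).to_dict()
    return CoStimDataset(df, design, tic)


class TestCvFilter:
    def test_zero_noise_all_retained(self, design):
        truth = generate_truth(design, [ArchetypeSpec("A_S1", BaseShape.SPIKE)])
        ds = add_noise(truth, NoiseModel(0.0, 0.0, 0.0, seed=0))
        assert cv_filter(ds) == {"A_S1"}

    def test_one_one_four_replicates_dropped(self):
        design = StimulationDesign((0, 5), (0,), 3)
        ds = _replicate_dataset(
            {"X_S1": {(0, 0): (1.0, 1.0, 4.0), (5, 0): (1.0, 1.0, 4.0)}}, design
        )
        # CV = sqrt(3)/2 ~ 0.866 at every condition
        assert cv_filter(ds) == set()

    def test_cv_exactly_at_threshold_dropped(self):
        design = StimulationDesign((0,), (0,), 3)
        ds = _replicate_dataset({"X_S1": {(0, 0): (3.0, 4.0, 5.0)}}, design)  # sd 1, mean 4
        assert cv_filter(ds, threshold=0.25) == set()
        assert cv_filter(ds, threshold=0.2501) == {"X_S1"}

    def test_no_multireplicate_condition_excluded_with_warning(self, caplog):
        design = StimulationDesign((0,), (0,), 3)
        ds = _replicate_dataset({"X_S1": {(0, 0): (3.0,)}}, design)
        with caplog.at_level("WARNING"):
            assert cv_filter(ds) == set()
        assert "X_S1" in caplog.text


class TestMissingnessFilter:
    def _surface(self, missing_conditions, design):
        vals = {
            "X_S1": {
                c: ((5.0, 5.0, 5.0) if c not in missing_conditions else (np.nan,) * 3)
                for c in design.conditions
            }
        }
        return average_replicates(_replicate_dataset(vals, design))

    def test_fully_observed_retained(self, design):
        from costim.ode import select_training_conditions

        training = select_training_conditions(design)
        surf = self._surface(set(), design)
        assert missingness_filter(surf, training) == {"X_S1"}

    def test_four_of_sixteen_missing_dropped(self, design):
        from costim.ode import select_training_conditions

        training = select_training_conditions(design)
        surf = self._surface(set(training[:4]), design)
        assert missingness_filter(surf, training) == set()

    def test_three_of_sixteen_missing_retained(self, design):
        from costim.ode import select_training_conditions

        training = select_training_conditions(design)
        surf = self._surface(set(training[:3]), design)
        assert missingness_filter(surf, training) == {"X_S1"}


class TestApMerge:
    def test_identical_pair_merged_known_member_chosen(self):
        t = np.array([1.0, 2.0, 3.0, 2.0])
        reps, cmap = ap_merge(
            {"P_S1": t, "P_S2": t.copy()},
            {"P_S1": "P", "P_S2": "P"},
            known_function={"P_S1"},
        )
        assert reps == ["P_S1"]
        assert cmap == {"P_S1": "P_S1", "P_S2": "P_S1"}

    def test_mutually_distant_trajectories_not_merged(self):
        trajs = {
            "P_S1": np.array([1.0, 10.0, 1.0, 1.0]),
            "P_S2": np.array([10.0, 1.0, 1.0, 10.0]),
            "P_S3": np.array([5.0, 5.0, 10.0, 1.0]),
        }
        reps, cmap = ap_merge(trajs, {k: "P" for k in trajs}, known_function=set())
        assert sorted(reps) == sorted(trajs)

    def test_identical_unknown_pair_plus_distinct_gives_two_clusters(self):
        t = np.array([1.0, 5.0, 1.0, 1.0])
        trajs = {"P_S1": t, "P_S2": t.copy(), "P_S9": np.array([9.0, 1.0, 9.0, 9.0])}
        reps, cmap = ap_merge(trajs, {k: "P" for k in trajs}, known_function=set())
        assert len(reps) == 2
        assert cmap["P_S1"] == cmap["P_S2"]
        assert cmap["P_S9"] == "P_S9"

    def test_different_proteins_never_merged(self):
        t = np.array([1.0, 2.0, 3.0])
        reps, _ = ap_merge(
            {"A_S1": t, "B_S1": t.copy()}, {"A_S1": "A", "B_S1": "B"}, set()
        )
        assert sorted(reps) == ["A_S1", "B_S1"]


def _random_prior(rng, n_proteins, n_edges):
    net = LogicNetwork()
    net.add_node("Stim", NodeRole.STIMULUS)
    names = [f"P{i}" for i in range(n_proteins)]
    for n in names:
        net.add_node(n, NodeRole.PROTEIN)
    net.add_edge("Stim", 1, names[0])
    while len(net.edges) < n_edges + 1:
        a, b = rng.choice(n_proteins, 2, replace=False)
        net.add_edge(names[a], int(rng.choice([1, -1])), names[b])
    return net, names


class TestBuildPepnet:
    def test_two_by_three_expansion(self):
        net = LogicNetwork()
        net.add_node("A", NodeRole.PROTEIN)
        net.add_node("B", NodeRole.PROTEIN)
        net.add_edge("A", 1, "B")
        out = build_pepnet(net, {"A": ["A_S1", "A_S2"], "B": ["B_S1", "B_S2", "B_S3"]})
        assert len(out.edges) == 6
        assert out.n_nodes == 5

    def test_unreplaced_protein_kept_unmeasured(self):
        net = LogicNetwork()
        net.add_node("A", NodeRole.PROTEIN)
        net.add_node("B", NodeRole.PROTEIN)
        net.add_edge("A", 1, "B")
        out = build_pepnet(net, {"A": ["A_S1"]})
        assert out.nodes["B"] == (NodeRole.PROTEIN, False)

    def test_absent_protein_in_assignment_is_error(self):
        net = LogicNetwork()
        net.add_node("A", NodeRole.PROTEIN)
        with pytest.raises(ValueError, match="absent protein"):
            build_pepnet(net, {"Z": ["Z_S1"]})

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_edge_count_matches_brute_force_product_sum(self, seed):
        rng = np.random.default_rng(seed)
        prior, names = _random_prior(rng, n_proteins=6, n_edges=8)
        assignment = {
            n: [f"{n}_S{j}" for j in range(rng.integers(0, 4))] for n in names
        }
        assignment = {k: v for k, v in assignment.items() if v}
        out = build_pepnet(prior, assignment)
        expected = sum(
            len(assignment.get(s, [s])) * len(assignment.get(t, [t]))
            for (s, _sg, t) in prior.edges
        )
        assert len(out.edges) == expected

    def test_shipped_fixture_reproduces_printed_model_size(self):
        peps = load_modeling_peptides()
        assignment = peps.groupby("protein")["ppep_id"].apply(list).to_dict()
        model = build_pepnet(load_prior_network(), assignment)
        assert model.n_nodes == 45
        assert model.n_interactions == 93


@pytest.fixture(scope="module")
def base_model():
    peps = load_modeling_peptides()
    assignment = peps.groupby("protein")["ppep_id"].apply(list).to_dict()
    return build_pepnet(load_prior_network(), assignment)


class TestApplyVariant:
    def test_empty_spec_is_identity(self, base_model):
        assert apply_variant(base_model, VariantSpec()) == base_model

    def test_both_mechanisms_match_printed_counts(self, base_model):
        model = apply_variant(base_model, VariantSpec(True, True))
        assert model.n_nodes == 39
        assert model.n_interactions == 73

    def test_idempotent_for_fixed_spec(self, base_model):
        spec = VariantSpec(True, True)
        once = apply_variant(base_model, spec)
        assert apply_variant(once, spec) == once

    def test_no_effect_group_removal_drops_their_edges(self, base_model):
        scheme = load_ensemble_scheme()
        edges = tuple(e for g in scheme.no_effect_groups.values() for e in g)
        model = apply_variant(base_model, VariantSpec(removed_edges=edges))
        assert model.n_interactions == base_model.n_interactions - len(edges)

    def test_removing_nonexistent_edge_is_error_naming_it(self, base_model):
        with pytest.raises(ValueError, match="Nope"):
            apply_variant(base_model, VariantSpec(removed_edges=(("Nope", 1, "Hot1_S153"),)))

    def test_variants_never_add_unmeasured_nodes(self, base_model):
        model = apply_variant(base_model, VariantSpec(True, True))
        unmeasured = {n for n, (r, m) in model.nodes.items() if r is NodeRole.PROTEIN}
        base_unmeasured = {
            n for n, (r, m) in base_model.nodes.items() if r is NodeRole.PROTEIN
        }
        assert unmeasured <= base_unmeasured


class TestEnumerateEnsemble:
    def test_default_scheme_enumerates_23_models(self, base_model):
        assert len(enumerate_ensemble(base_model)) == 23

    def test_base_only_scheme_gives_single_model(self, base_model):
        scheme = EnsembleScheme(mechanism_combos=[(False, False)])
        assert len(enumerate_ensemble(base_model, scheme)) == 1

    def test_enumeration_arithmetic(self, base_model):
        scheme = load_ensemble_scheme()
        small = EnsembleScheme(
            mechanism_combos=[(False, False), (True, True)],
            no_effect_groups={},
            single_removals=scheme.single_removals[:3],
        )
        assert len(enumerate_ensemble(base_model, small)) == 5

    def test_duplicate_specs_collapsed_with_warning(self, base_model, caplog):
        scheme = EnsembleScheme(
            mechanism_combos=[(False, False), (False, False)],
        )
        with caplog.at_level("WARNING"):
            models = enumerate_ensemble(base_model, scheme)
        assert len(models) == 1 and "duplicates" in caplog.text
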