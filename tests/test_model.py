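"""Network construction, the E. coli builders and file round trips."""

import json

import numpy as np
import pytest

import thermoreg as tr
from thermoreg.model import GAS_CONSTANT_KJ, ModelError


class TestBuildNetwork:
    def test_single_reaction_partition(self):
        net, state = tr.build_network(
            [("R1", {"A": -1, "B": 1})],
            [("A", True, 4.0), ("B", False, None)],
        )
        assert net.n_reactions == 1
        assert net.n_metabolites == 2
        assert net.n_variable == 1
        assert net.stoich_variable.tolist() == [[1.0]]
        assert state.concentrations[0] == pytest.approx(4e-3)

    def test_chain_sign_convention(self):
        net, _ = tr.build_network(
            [("R1", {"A": -1, "B": 1}), ("R2", {"B": -1, "C": 1})],
            [("A", True, 4.0), ("B", False, None), ("C", True, 1.0)],
        )
        assert net.stoich_variable.tolist() == [[1.0, -1.0]]

    def test_partition_reassembly(self, full_model):
        net, _, _ = full_model
        rebuilt = np.empty_like(net.stoich)
        rebuilt[net.variable_mask] = net.stoich_variable
        rebuilt[~net.variable_mask] = net.stoich_boundary
        np.testing.assert_array_equal(rebuilt, net.stoich)

    @pytest.mark.parametrize(
        "reactions, metabolites, match",
        [
            (
                [("R1", {"A": -1}), ("R1", {"A": 1})],
                [("A", True, 1.0)],
                "duplicate reaction",
            ),
            ([("R1", {})], [("A", True, 1.0)], "no nonzero"),
            (
                [("R1", {"A": -1, "B": 1})],
                [("A", False, None), ("B", False, None)],
                "underdetermined",
            ),
            ([("R1", {"A": -1, "B": 1})], [("A", True, None), ("B", False, None)],
             "positive concentration"),
        ],
    )
    def test_construction_errors(self, reactions, metabolites, match):
        with pytest.raises(ModelError, match=match):
            tr.build_network(reactions, metabolites)

    def test_underdetermined_error_names_counts(self):
        with pytest.raises(ModelError, match="2 variable.*1 reactions"):
            tr.build_network(
                [("R1", {"A": -1, "B": 1})],
                [("A", False, None), ("B", False, None)],
            )


class TestEcoliBuilders:
    def test_glycolysis_ppp_tca_counts(self):
        net, _ = tr.build_ecoli_pathway("glycolysis_ppp_tca")
        assert net.n_reactions == 29
        assert net.n_metabolites == 47
        assert net.n_boundary == 20
        assert net.n_variable == 27

    def test_gluconeogenesis_reaction_count(self):
        net, _ = tr.build_ecoli_pathway("gluconeogenesis")
        assert net.n_reactions == 10

    def test_boundary_concentrations(self):
        net, state = tr.build_ecoli_pathway("glycolysis_ppp_tca")
        conc = dict(zip(net.metabolite_ids, state.concentrations * 1e3))  # mM
        assert conc["atp"] == pytest.approx(9.6)
        assert conc["adp"] == pytest.approx(0.56)
        assert conc["h2o"] == pytest.approx(55.5e3)
        assert conc["nad"] / conc["nadh"] == pytest.approx(31.3, rel=1e-2)

    @pytest.mark.parametrize("condition, ratio", [
        ("high_nad_low_nadp", 0.02),
        ("high_nad_high_nadp", 31.3),
    ])
    def test_nadp_ratio_follows_condition(self, condition, ratio):
        net, state = tr.build_ecoli_pathway("glycolysis_ppp_tca", condition)
        conc = dict(zip(net.metabolite_ids, state.concentrations))
        assert conc["nadp"] / conc["nadph"] == pytest.approx(ratio, rel=1e-6)
        # NAD pool identical across conditions
        assert conc["nad"] / conc["nadh"] == pytest.approx(31.3, rel=1e-2)

    def test_builder_determinism(self):
        a_net, a_state = tr.build_ecoli_pathway("glycolysis_ppp_tca")
        b_net, b_state = tr.build_ecoli_pathway("glycolysis_ppp_tca")
        assert a_net.reaction_ids == b_net.reaction_ids
        assert a_net.metabolite_ids == b_net.metabolite_ids
        np.testing.assert_array_equal(a_net.stoich, b_net.stoich)
        np.testing.assert_array_equal(a_state.concentrations, b_state.concentrations)

    def test_pfk_off_pins_activity(self):
        net, state = tr.build_ecoli_pathway("glycolysis_ppp_tca", pfk_off=True)
        assert state.activities[net.reaction_index("PFK")] == 0.0
        assert np.all(np.delete(state.activities, net.reaction_index("PFK")) == 1.0)

    def test_unknown_name_and_condition(self):
        with pytest.raises(ModelError, match="unknown pathway"):
            tr.build_ecoli_pathway("nope")
        with pytest.raises(ModelError, match="unknown condition"):
            tr.build_ecoli_pathway("glycolysis_tca", "nope")


class TestToyPathways:
    def test_chain_variable_count(self, toy_chain):
        net, _, thermo = toy_chain
        assert net.n_variable == 1
        np.testing.assert_array_equal(thermo.equilibrium_constants, [1.0, 1.0])

    def test_branch_hub_row(self):
        net, _, _ = tr.generate_toy_pathway("branch", 3, None, (4.0, 1.0, 1.0))
        hub = net.stoich[net.metabolite_index("HUB")]
        assert hub.tolist() == [1.0, -1.0, -1.0]

    def test_cycle_has_more_reactions_than_intermediates(self):
        net, _, _ = tr.generate_toy_pathway("cycle")
        assert net.n_reactions == 8
        assert net.n_variable == 7

    @pytest.mark.parametrize("kwargs", [
        dict(topology="chain", length=2, K_values=(0.0, 1.0)),
        dict(topology="chain", length=2, boundary_values=(0.0, 1.0)),
        dict(topology="chain", length=0),
        dict(topology="mobius"),
    ])
    def test_invalid_toy_inputs(self, kwargs):
        with pytest.raises(ModelError):
            tr.generate_toy_pathway(**kwargs)


class TestFileIO:
    def test_model_round_trip(self, toy_chain, tmp_path):
        net, state, _ = toy_chain
        path = tmp_path / "model.json"
        tr.write_model(path, net, state)
        net2, state2 = tr.load_model(path)
        assert net2.reaction_ids == net.reaction_ids
        assert net2.metabolite_ids == net.metabolite_ids
        np.testing.assert_array_equal(net2.stoich, net.stoich)
        np.testing.assert_array_equal(net2.variable_mask, net.variable_mask)
        np.testing.assert_allclose(state2.concentrations, state.concentrations)
        np.testing.assert_array_equal(state2.activities, state.activities)

    def test_thermo_from_delta_g(self, toy_chain, tmp_path):
        net, _, _ = toy_chain
        path = tmp_path / "thermo.tsv"
        rt = GAS_CONSTANT_KJ * 298.15
        path.write_text(
            "reaction_id\tdelta_g_prime_kj_mol\n"
            f"R1\t0.0\nR2\t{-rt * np.log(2)}\n"
        )
        thermo = tr.load_thermo(path, net)
        assert thermo.equilibrium_constants[0] == pytest.approx(1.0)
        assert thermo.equilibrium_constants[1] == pytest.approx(2.0)

    def test_thermo_disagreement_rejected(self, toy_chain, tmp_path):
        net, _, _ = toy_chain
        path = tmp_path / "thermo.tsv"
        path.write_text(
            "reaction_id\tK\tdelta_g_prime_kj_mol\nR1\t2.0\t0.0\nR2\t1.0\t0.0\n"
        )
        with pytest.raises(ModelError, match="disagree"):
            tr.load_thermo(path, net)

    def test_targets_default_to_one_mM(self, toy_chain, tmp_path):
        net, _, _ = toy_chain
        path = tmp_path / "targets.tsv"
        path.write_text("metabolite_id\tconcentration_mM\nX1\t1.5\n")
        targets = tr.load_targets(path, net)
        assert targets[0] == pytest.approx(1.5e-3)
        # unmeasured species on a larger model default to 1.0 mM
        full, _ = tr.build_ecoli_pathway("gluconeogenesis")
        path.write_text("metabolite_id\tconcentration_mM\noaa\t0.5\n")
        t = tr.load_targets(path, full)
        assert t[full.variable_ids.index("oaa")] == pytest.approx(0.5e-3)
        others = [v for i, v in enumerate(t) if full.variable_ids[i] != "oaa"]
        assert np.allclose(others, 1e-3)

    def test_schema_violation_reports_field(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"metabolites": []}))
        with pytest.raises(ModelError, match="reactions"):
            tr.load_model(path)
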