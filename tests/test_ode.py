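"""Hill normalization, training selection, logic-ODE semantics, fit, AIC."""

import math

import numpy as np
import pandas as pd
import pytest

from costim.core import LogicNetwork, NodeRole, StimulationDesign
from costim.ode import (
    OdeParams,
    OptimizerConfig,
    aic,
    compare_models,
    fit,
    hill_normalize,
    mse,
    select_training_conditions,
    simulate,
    to_logic_ode,
)


class TestHillNormalize:
    def test_midpoint_maps_to_half(self):
        out = hill_normalize(np.array([1.0, 2.0, 4.0]), n=4, k=2.0)
        assert out[1] == pytest.approx(0.5)

    def test_twice_k_gives_sixteen_seventeenths(self):
        out = hill_normalize(np.array([4.0]), n=4, k=2.0)
        assert out[0] == pytest.approx(16 / 17)

    def test_limits(self):
        out = hill_normalize(np.array([1e-9, 1e9]), n=4, k=1.0)
        assert out[0] == pytest.approx(0.0, abs=1e-6)
        assert out[1] == pytest.approx(1.0, abs=1e-6)

    def test_default_k_is_median(self):
        vals = np.array([1.0, 3.0, 9.0])
        assert hill_normalize(vals, n=4)[1] == pytest.approx(0.5)

    def test_degenerate_identical_values_error(self):
        with pytest.raises(ValueError, match="identical"):
            hill_normalize(np.array([2.0, 2.0, 2.0]))


class TestSelectTrainingConditions:
    def test_default_design_yields_16(self, design):
        conds = select_training_conditions(design)
        assert len(conds) == 16
        assert len(set(conds)) == 16

    def test_single_point_design(self):
        assert select_training_conditions(StimulationDesign((0,), (0,), 1)) == [(0, 0)]

    def test_three_by_three_union_arithmetic(self):
        design = StimulationDesign((0, 5, 10), (0, 5, 10), 1)
        conds = select_training_conditions(design)
        brute = {(t, 0) for t in (0, 5, 10)} | {(0, t) for t in (0, 5, 10)} | {
            (t, t) for t in (0, 5, 10)
        }
        assert set(conds) == brute and len(conds) == 7


def _single_edge_system(sign=1):
    net = LogicNetwork()
    net.add_node("U", NodeRole.STIMULUS)
    net.add_node("X", NodeRole.PPEP, True)
    net.add_edge("U", sign, "X")
    return to_logic_ode(net)


class TestLogicOdeSemantics:
    def test_full_activation_and_full_silence_endpoints(self):
        system = _single_edge_system()
        params = system.default_params(tau=1.0, n=4, k=0.5)
        on = simulate(system, params, {"U": 1.0}, [0, 100.0])
        off = simulate(system, params, {"U": 0.0}, [0, 100.0])
        assert on["X"].iloc[-1] == pytest.approx(1.0, abs=1e-5)
        assert off["X"].iloc[-1] == pytest.approx(0.0, abs=1e-6)

    def test_intermediate_clamp_fixed_point_closed_form(self):
        system = _single_edge_system()
        params = system.default_params(tau=1.0, n=4, k=0.5)
        traj = simulate(system, params, {"U": 0.5}, [0, 200.0])
        assert traj["X"].iloc[-1] == pytest.approx(0.53125, abs=1e-5)

    def test_inhibition_only_input_at_one_silences_target(self):
        system = _single_edge_system(sign=-1)
        params = system.default_params(tau=1.0, n=4, k=0.5)
        traj = simulate(system, params, {"U": 1.0}, [0, 100.0], y0={"X": 0.8})
        assert traj["X"].iloc[-1] == pytest.approx(0.0, abs=1e-5)

    def test_zero_input_network_is_constant(self, caplog):
        net = LogicNetwork()
        net.add_node("X", NodeRole.PPEP, True)
        with caplog.at_level("WARNING"):
            system = to_logic_ode(net)
        traj = simulate(system, system.default_params(), {}, [0, 10.0], y0={"X": 0.4})
        assert np.allclose(traj["X"], 0.4)
        assert "held constant" in caplog.text

    def test_trajectories_bounded_in_unit_interval(self, toy_network):
        system = to_logic_ode(toy_network)
        params = system.default_params(tau=1.5, n=6, k=0.3)
        traj = simulate(system, params, {"NaCl": 1.0, "Phe": 1.0}, np.linspace(0, 45, 40))
        assert (traj.to_numpy() >= 0).all() and (traj.to_numpy() <= 1).all()

    def test_fast_tau_tracks_input_within_first_grid_point(self):
        system = _single_edge_system()
        params = system.default_params(tau=50.0, n=4, k=0.5)
        traj = simulate(system, params, {"U": 1.0}, [0, 1.0, 5.0])
        assert traj["X"].iloc[1] == pytest.approx(1.0, abs=1e-3)

    def test_grid_refinement_changes_nothing_material(self, toy_network):
        system = to_logic_ode(toy_network)
        params = system.default_params()
        coarse = simulate(system, params, {"NaCl": 1.0, "Phe": 0.0}, [0, 10, 45.0])
        fine = simulate(system, params, {"NaCl": 1.0, "Phe": 0.0}, np.linspace(0, 45, 200))
        for t in (10.0, 45.0):
            assert coarse.loc[t, "B"] == pytest.approx(
                fine.loc[fine.index[np.argmin(np.abs(fine.index - t))], "B"], abs=1e-3
            )


from conftest import boolean_eval as _boolean_eval


class TestBooleanLimit:
    def test_two_layer_cascade_matches_boolean_oracle(self):
        net = LogicNetwork()
        for s in ("I1", "I2", "I3"):
            net.add_node(s, NodeRole.STIMULUS)
        for n in ("X", "Y", "Z"):
            net.add_node(n, NodeRole.PPEP, True)
        net.add_edge("I1", 1, "X")
        net.add_edge("I2", -1, "X")
        net.add_and_gate("and1", [("I2", 1), ("I3", 1)], "Y")
        net.add_edge("X", 1, "Z")
        net.add_edge("Y", 1, "Z")
        system = to_logic_ode(net)
        params = system.default_params(tau=2.0, n=10, k=0.5)
        for bits in range(8):
            inputs = {f"I{i+1}": (bits >> i) & 1 for i in range(3)}
            expected = _boolean_eval(net, inputs)
            traj = simulate(system, params, {k: float(v) for k, v in inputs.items()}, [0, 150.0])
            for node in ("X", "Y", "Z"):
                assert traj[node].iloc[-1] == pytest.approx(expected[node], abs=1e-4), (
                    inputs,
                    node,
                )


class TestMseAic:
    def test_mse_hand_computed_examples(self):
        sim = pd.DataFrame({"X": [1.0, 1.0, 1.0, 1.0]})
        data = pd.DataFrame({"X": [1.0, 1.1, 1.2, 1.3]})
        assert mse(sim, data, ["X"]) == pytest.approx(0.035)
        assert mse(sim, sim, ["X"]) == 0.0

    def test_mse_ignores_missing_points(self):
        sim = pd.DataFrame({"X": [1.0, 1.0]})
        data = pd.DataFrame({"X": [0.9, np.nan]})
        assert mse(sim, data, ["X"]) == pytest.approx(0.01)

    def test_mse_empty_subset_error(self):
        sim = pd.DataFrame({"X": [1.0]})
        with pytest.raises(ValueError, match="empty"):
            mse(sim, sim, [])

    def test_aic_arithmetic(self):
        assert aic(1.0, 50, 7) == pytest.approx(14.0)
        assert aic(0.25, 100, 10) == pytest.approx(100 * math.log(0.25) + 20)

    def test_aic_parameter_penalty_is_two_per_param(self):
        assert aic(0.5, 100, 11) - aic(0.5, 100, 10) == pytest.approx(2.0)

    def test_aic_monotone_in_mse(self):
        assert aic(0.2, 100, 5) > aic(0.1, 100, 5)

    def test_zero_mse_returns_neg_inf_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert aic(0.0, 10, 2) == -math.inf


def _toy_training_data(system, params, design):
    conds = select_training_conditions(design)
    rows, meas = [], []
    for tn, tp in conds:
        clamp = {"NaCl": 1.0 if tn > 0 else 0.0, "Phe": 1.0 if tp > 0 else 0.0}
        t = max(tn, tp)
        traj = simulate(system, params, clamp, [0.0, float(t)])
        rows.append({"TR:NaCl": int(tn > 0), "TR:Phe": int(tp > 0), "time": t})
        meas.append(traj.iloc[-1][system.species])
    return pd.DataFrame(rows), pd.DataFrame(meas).reset_index(drop=True)


@pytest.fixture(scope="module")
def training():
    toy = LogicNetwork()
    toy.add_node("NaCl", NodeRole.STIMULUS)
    toy.add_node("Phe", NodeRole.STIMULUS)
    for n in "ABCD":
        toy.add_node(n, NodeRole.PPEP, True)
    toy.add_edge("NaCl", 1, "A")
    toy.add_edge("A", 1, "B")
    toy.add_edge("Phe", 1, "C")
    toy.add_edge("C", -1, "B")
    toy.add_edge("B", 1, "D")
    system = to_logic_ode(toy)
    true = OdeParams(
        tau={"A": 0.8, "B": 0.3, "C": 0.5, "D": 0.15},
        hill_n={e: 3.0 for e in system.edge_list},
        hill_k={e: 0.5 for e in system.edge_list},
    )
    conds, meas = _toy_training_data(system, true, StimulationDesign())
    return system, true, conds, meas


class TestFit:
    def test_same_seed_gives_identical_result(self, training):
        system, _true, conds, meas = training
        cfg = OptimizerConfig(n_restarts=1, eval_budget=400, seed=11)
        r1 = fit(system, conds, meas, cfg)
        r2 = fit(system, conds, meas, cfg)
        assert r1.mse == r2.mse
        assert r1.params.tau == r2.params.tau

    def test_more_restarts_never_worse(self, training):
        system, _true, conds, meas = training
        r1 = fit(system, conds, meas, OptimizerConfig(n_restarts=1, eval_budget=400, seed=5))
        r3 = fit(system, conds, meas, OptimizerConfig(n_restarts=3, eval_budget=400, seed=5))
        assert r3.mse <= r1.mse + 1e-12
        assert len(r3.best_per_restart) == 3

    def test_aic_consistent_with_mse_and_params(self, training):
        system, _true, conds, meas = training
        res = fit(system, conds, meas, OptimizerConfig(n_restarts=1, eval_budget=400, seed=2))
        if res.mse > 0:
            assert res.aic == pytest.approx(
                res.n_points * math.log(res.mse) + 2 * res.n_params
            )


class TestCompareModels:
    def _result(self, mse_value, n_params, nodes=("X",)):
        from costim.ode import FitResult

        return FitResult(
            params=OdeParams({}, {}, {}),
            mse=mse_value,
            n_points=100,
            n_params=n_params,
            aic=aic(mse_value, 100, n_params),
            seed=0,
            evals_used=0,
            best_per_restart=[mse_value],
            node_subset=list(nodes),
        )

    def test_equal_mse_fewer_params_ranks_first(self):
        table = compare_models(
            {"big": self._result(0.1, 20), "small": self._result(0.1, 10)}, ["X"]
        )
        assert table.iloc[0]["model_id"] == "small"

    def test_singleton_table(self):
        table = compare_models({"only": self._result(0.2, 5)}, ["X"])
        assert len(table) == 1

    def test_ranking_matches_hand_computed_aics(self):
        fits = {
            "a": self._result(0.05, 30),
            "b": self._result(0.06, 10),
            "c": self._result(0.30, 5),
        }
        table = compare_models(fits, ["X"])
        expected = sorted(fits, key=lambda m: fits[m].aic)
        assert table["model_id"].tolist() == expected

    def test_inconsistent_node_subsets_error(self):
        with pytest.raises(ValueError, match="evaluated on"):
            compare_models(
                {"a": self._result(0.1, 5, nodes=("X",)), "b": self._result(0.1, 5, nodes=("Y",))},
                ["X"],
            )
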