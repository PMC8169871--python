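"""Discretization, the iMAT MILP, the enumeration oracle, activity calls."""

import numpy as np
import pandas as pd
import pytest

from metactivity.expression import ExpressionMatrix
from metactivity.imat_core import (
    ActivityMatrix,
    ImatError,
    ReactionStateSet,
    Thresholds,
    assign_states,
    call_activity,
    enumerate_optimum,
    pooled_thresholds,
    predict_activity,
    reaction_expression,
    robust_activity,
    solve_imat,
)
from metactivity.model_io import MetabolicModel, Metabolite, Reaction, parse_gpr
from metactivity.synthetic_data import NetworkSpec, make_toy_network


def _expr(values: np.ndarray) -> ExpressionMatrix:
    n_genes, n_samples = values.shape
    samples = [f"s{i}" for i in range(n_samples)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=[f"g{i}" for i in range(n_genes)],
                            columns=samples),
        metadata=pd.DataFrame({"group": ["x"] * n_samples}, index=samples))


def _stoich_residual(model: MetabolicModel, flux: dict) -> float:
    residual = {m.id: 0.0 for m in model.metabolites}
    for rxn in model.reactions:
        for met, coef in rxn.stoichiometry.items():
            residual[met] += coef * flux[rxn.id]
    return max(abs(v) for v in residual.values())


# ---------------------------------------------------------------------------
# Thresholds and states
# ---------------------------------------------------------------------------

def test_pooled_thresholds_linear_interpolation():
    th = pooled_thresholds(_expr(np.arange(1.0, 9.0).reshape(2, 4)))
    assert th.q25 == pytest.approx(2.75)
    assert th.q75 == pytest.approx(6.25)


def test_constant_matrix_collapses_thresholds():
    th = pooled_thresholds(_expr(np.full((3, 4), 2.5)))
    assert th.q25 == th.q75 == 2.5
    # strict inequalities leave everything moderate
    states = assign_states({"r": 2.5}, th)
    assert not states.high and not states.low


def test_at_most_quarter_exceed_q75():
    rng = np.random.default_rng(0)
    values = rng.normal(size=(13, 7))
    th = pooled_thresholds(_expr(values))
    # up to one extra value from interpolation between order statistics
    assert (values > th.q75).mean() <= 0.25 + 1.0 / values.size


def test_reaction_expression_gpr_mapping(cholesterol_model):
    gene_vals = {"ACAT2": 2.0, "HMGCS1": 5.0, "HMGCR": 4.0, "DHCR24": 1.0,
                 "DHCR7": 9.0, "CYP46A1": 3.0, "HSD3B7": 6.0, "SOAT1": 7.0}
    vals = reaction_expression(cholesterol_model, gene_vals)
    assert vals["R_HMGSYN"] == 2.0  # AND -> min
    assert vals["R_HMGCR"] == 4.0
    assert "EX_accoa" not in vals  # no GPR, no value


def test_reaction_expression_skips_missing_genes(caplog):
    model = MetabolicModel(
        metabolites=(Metabolite("A"),),
        reactions=(Reaction("r", {"A": 1.0}, 0, 1, gpr=parse_gpr("g1 or g2")),),
        genes=("g1", "g2"))
    with caplog.at_level("INFO"):
        vals = reaction_expression(model, {"g1": 2.0})
    assert vals == {}


def test_assign_states_strict_inequalities():
    th = Thresholds(2.75, 6.25)
    states = assign_states({"hi": 7.0, "edge": 6.25, "lo": 1.0}, th)
    assert states.high == {"hi"}
    assert states.low == {"lo"}
    # boundary value and missing reactions are moderate


# ---------------------------------------------------------------------------
# MILP on the worked 3-reaction chain
# ---------------------------------------------------------------------------

def test_high_reaction_forced_to_carry_flux(chain_model):
    states = ReactionStateSet("s", frozenset({"r_ab"}), frozenset())
    sol = solve_imat(chain_model, states, epsilon=1.0)
    assert sol.objective == 1
    assert sol.flux["r_ab"] >= 1.0
    assert call_activity(sol) == {"EX_in": 1, "r_ab": 1, "EX_out": 1}


def test_low_reaction_silences_chain(chain_model):
    states = ReactionStateSet("s", frozenset(), frozenset({"r_ab"}))
    sol = solve_imat(chain_model, states, epsilon=1.0)
    assert sol.objective == 1
    assert all(abs(v) < 1e-9 for v in sol.flux.values())


def test_series_conflict_satisfies_only_one(chain_model):
    states = ReactionStateSet("s", frozenset({"EX_in"}), frozenset({"r_ab"}))
    assert solve_imat(chain_model, states, 1.0).objective == 1
    assert enumerate_optimum(chain_model, states, 1.0) == 1


def test_empty_states_give_zero_objective(chain_model):
    states = ReactionStateSet("s", frozenset(), frozenset())
    assert enumerate_optimum(chain_model, states, 1.0) == 0
    assert solve_imat(chain_model, states, 1.0).objective == 0


def test_call_activity_thresholding():
    sol = solve_imat.__wrapped__ if False else None  # direct construction
    from metactivity.imat_core import ImatSolution

    sol = ImatSolution(flux={"r1": 1.0, "r2": 0.0, "r3": 1e-9},
                       high_indicators={}, low_indicators={},
                       objective=0, status="optimal", epsilon=1.0)
    assert call_activity(sol, tol=1e-6) == {"r1": 1, "r2": 0, "r3": 0}
    sol.status = "infeasible"
    with pytest.raises(ImatError):
        call_activity(sol)


# ---------------------------------------------------------------------------
# Oracle equivalence and invariants on random toy networks
# ---------------------------------------------------------------------------

def _random_instance(seed: int):
    rng = np.random.default_rng(seed)
    spec = NetworkSpec(
        n_linear_reactions=int(rng.integers(3, 7)),
        n_branches=int(rng.integers(0, 3)),
        fraction_with_and_gprs=0.3,
        include_media_reactions=bool(rng.random() < 0.5),
    )
    model, _ = make_toy_network(spec, seed=seed)
    rxn_ids = list(model.reaction_ids)
    k = min(len(rxn_ids), int(rng.integers(1, 7)))
    chosen = rng.choice(rxn_ids, size=k, replace=False)
    split = rng.random(k) < 0.5
    high = frozenset(np.array(chosen)[split].tolist())
    low = frozenset(np.array(chosen)[~split].tolist())
    states = ReactionStateSet(f"seed{seed}", high, low)
    return model, states


@pytest.mark.parametrize("seed", range(40))
def test_milp_matches_enumeration_oracle(seed):
    model, states = _random_instance(seed)
    milp_obj = solve_imat(model, states, epsilon=1.0).objective
    oracle_obj = enumerate_optimum(model, states, epsilon=1.0)
    assert milp_obj == oracle_obj


@pytest.mark.parametrize("seed", range(0, 40, 5))
def test_solutions_satisfy_mass_balance_and_bounds(seed):
    model, states = _random_instance(seed)
    sol = solve_imat(model, states, epsilon=1.0)
    assert _stoich_residual(model, sol.flux) <= 1e-6
    for rxn in model.reactions:
        v = sol.flux[rxn.id]
        assert rxn.lower_bound - 1e-9 <= v <= rxn.upper_bound + 1e-9


def test_growing_high_set_changes_objective_by_at_most_one():
    model, _ = make_toy_network(NetworkSpec(6, 1), seed=3)
    base = ReactionStateSet("s", frozenset({"R1"}), frozenset())
    obj0 = solve_imat(model, base, 1.0).objective
    grown = ReactionStateSet("s", frozenset({"R1", "EX_out"}), frozenset())
    obj1 = solve_imat(model, grown, 1.0).objective
    assert obj0 <= obj1 <= obj0 + 1


def test_objective_invariant_under_common_scaling():
    model, _ = make_toy_network(NetworkSpec(5, 1), seed=11)
    states = ReactionStateSet("s", frozenset({"R1"}), frozenset({"B1a"}))
    obj = solve_imat(model, states, epsilon=1.0).objective
    from dataclasses import replace
    scaled = replace(model, reactions=tuple(
        replace(r, lower_bound=7.0 * r.lower_bound,
                upper_bound=7.0 * r.upper_bound) for r in model.reactions))
    assert solve_imat(scaled, states, epsilon=7.0).objective == obj


def test_epsilon_above_bounds_blocks_high_indicators(chain_model):
    states = ReactionStateSet("s", frozenset({"r_ab"}), frozenset())
    sol = solve_imat(chain_model, states, epsilon=100.0)
    assert sol.objective == 0


def test_enumeration_cap_enforced(chain_model):
    states = ReactionStateSet(
        "s", frozenset(f"r{i}" for i in range(17)), frozenset())
    with pytest.raises(ValueError, match="capped"):
        enumerate_optimum(chain_model, states, 1.0)


def test_robust_mode_agrees_on_forced_chain(chain_model):
    states = ReactionStateSet("s", frozenset({"r_ab"}), frozenset())
    robust = robust_activity(chain_model, states, epsilon=1.0)
    assert robust == {"EX_in": 1, "r_ab": 1, "EX_out": 1}


# ---------------------------------------------------------------------------
# Activity matrix container and the per-sample driver
# ---------------------------------------------------------------------------

def test_activity_matrix_tsv_round_trip(tmp_path):
    am = ActivityMatrix(
        reactions=("r1", "r2"), samples=("s1", "s2", "s3"),
        values=np.array([[1, 0, 1], [0, 0, 1]]),
        provenance={"epsilon": 1.0, "solver": "scipy-highs"})
    path = tmp_path / "act.tsv"
    am.write_tsv(path)
    loaded = ActivityMatrix.read_tsv(path)
    assert loaded.reactions == am.reactions
    assert loaded.samples == am.samples
    np.testing.assert_array_equal(loaded.values, am.values)
    assert loaded.provenance["solver"] == "scipy-highs"


def test_predict_activity_routes_flux_by_expression(chain_model):
    """High expression on the conversion gene keeps the chain active."""
    model = MetabolicModel(
        metabolites=chain_model.metabolites,
        reactions=tuple(
            Reaction(r.id, dict(r.stoichiometry), r.lower_bound, r.upper_bound,
                     gpr=parse_gpr("gA") if r.id == "r_ab" else None)
            for r in chain_model.reactions),
        genes=("gA",))
    rng = np.random.default_rng(0)
    values = np.vstack([np.full(4, 9.0),  # gA high everywhere
                        rng.normal(5, 0.1, size=(30, 4))])
    samples = [f"s{i}" for i in range(4)]
    em = ExpressionMatrix(
        values=pd.DataFrame(values, index=["gA"] + [f"n{i}" for i in range(30)],
                            columns=samples),
        metadata=pd.DataFrame({"group": ["x"] * 4}, index=samples))
    activity = predict_activity(model, em, epsilon=1.0)
    assert activity.values.shape == (3, 4)
    assert (activity.to_frame().loc["r_ab"] == 1).all()
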