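"""iMAT, draft extraction, E-Flux and the full contextualization pipeline."""

import numpy as np
import pytest

from hepatoflux import (
    Category,
    IMATParams,
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionWeights,
    SimulationSpec,
    build_context_model,
    categorize,
    eflux,
    extract_context,
    fastcc,
    imat,
    make_toy_model,
    reaction_weights,
    simulate_expression,
)
from hepatoflux.reference import imat_bruteforce


@pytest.fixture
def branched():
    """EX_A -> A -> B; B -> C -> EX_C; B -> D -> EX_D."""
    mets = [
        Metabolite(m, compartment="e" if m.endswith("_e") else "c")
        for m in ["A_e", "A", "B", "C", "D", "C_e", "D_e"]
    ]
    rxns = [
        Reaction("EX_A", {"A_e": -1.0}, -10.0, 0.0, "exchange", is_exchange=True),
        Reaction("TA", {"A_e": -1.0, "A": 1.0}, 0.0, 10.0, "s1", gpr="gA"),
        Reaction("AB", {"A": -1.0, "B": 1.0}, 0.0, 10.0, "s1", gpr="gB"),
        Reaction("BC", {"B": -1.0, "C": 1.0}, 0.0, 10.0, "s2", gpr="gC"),
        Reaction("BD", {"B": -1.0, "D": 1.0}, 0.0, 10.0, "s3", gpr="gD"),
        Reaction("TC", {"C": -1.0, "C_e": 1.0}, 0.0, 10.0, "s2", gpr="gC2"),
        Reaction("TD", {"D": -1.0, "D_e": 1.0}, 0.0, 10.0, "s3", gpr="gD2"),
        Reaction("EX_C", {"C_e": -1.0}, 0.0, 10.0, "exchange", is_exchange=True),
        Reaction("EX_D", {"D_e": -1.0}, 0.0, 10.0, "exchange", is_exchange=True),
    ]
    return MetabolicModel(mets, rxns, id="branched")


def _cats(model, high=(), low=()):
    cats = {r.id: Category.MODERATE for r in model.reactions}
    for r in high:
        cats[r] = Category.HIGH
    for r in low:
        cats[r] = Category.LOW
    return cats


def test_imat_silences_low_branch(branched):
    cats = _cats(branched, high=["AB"], low=["BD"])
    sol = imat(branched, cats)
    assert sol.objective == 2
    assert sol.silenced_low == {"BD"}
    assert abs(sol.fluxes["BD"]) <= 1e-6
    assert sol.fluxes["AB"] >= 1.0 - 1e-6


def test_imat_empty_sets_objective_zero(branched):
    sol = imat(branched, _cats(branched))
    assert sol.objective == 0


def test_imat_blocked_high_cannot_activate(branched):
    m = branched.copy()
    m.metabolites.append(Metabolite("E", compartment="c"))
    m.reactions.append(
        Reaction("DEAD", {"D": -1.0, "E": 1.0}, 0.0, 10.0, "s3", gpr="gE")
    )
    m._validate()
    sol = imat(m, _cats(m, high=["DEAD"]))
    assert sol.objective == 0
    assert sol.satisfied_high == set()


def test_imat_matches_bruteforce_on_branched(branched):
    cats = _cats(branched, high=["AB", "BC"], low=["BD", "TD"])
    sol = imat(branched, cats)
    assert sol.objective == imat_bruteforce(branched, cats)


@pytest.mark.parametrize("seed", range(5))
def test_imat_matches_bruteforce_on_toys(seed):
    spec = SimulationSpec(seed=seed, n_pathways=4, reactions_per_pathway=4,
                          chains_per_pathway=1)
    model, _ = make_toy_model(spec)
    expr, meta, _ = simulate_expression(model, spec)
    w = reaction_weights(model, expr, group="case", group_metadata=meta)
    cats, _ = categorize(w)
    sol = imat(model, cats)
    assert sol.objective == imat_bruteforce(model, cats)


def test_epsilon_monotonicity(branched):
    """Enlarging epsilon can only decrease the iMAT objective."""
    cats = _cats(branched, high=["AB", "BC", "TD"], low=["BD"])
    objs = [
        imat(branched, cats, IMATParams(epsilon=e)).objective
        for e in (0.5, 1.0, 5.0, 10.0, 10.5)
    ]
    assert objs == sorted(objs, reverse=True)


def test_extract_removes_silenced_branch(branched):
    cats = _cats(branched, high=["AB"], low=["BD"])
    sol = imat(branched, cats)
    draft, prov = extract_context(branched, cats, sol)
    assert "BD" not in draft
    assert "TD" not in draft  # downstream of the silenced branch, blocked
    assert "EX_D" not in draft
    assert "BC" in draft and "EX_C" in draft
    assert prov["BD"] == "removed-low"
    assert prov["TD"] == "removed-blocked"


def test_all_moderate_extraction_is_fastcc(toy_model):
    cats = _cats(toy_model)
    sol = imat(toy_model, cats)
    draft, _ = extract_context(toy_model, cats, sol)
    assert set(draft.reaction_ids) == fastcc(toy_model)


def test_extraction_is_flux_consistent(toy_model):
    spec = SimulationSpec(seed=0)
    expr, meta, _ = simulate_expression(toy_model, spec)
    w = reaction_weights(toy_model, expr, group="case", group_metadata=meta)
    cats, _ = categorize(w)
    sol = imat(toy_model, cats)
    draft, _ = extract_context(toy_model, cats, sol)
    assert fastcc(draft) == set(draft.reaction_ids)


def test_eflux_max_normalized_scaling(chain_model):
    w = ReactionWeights({"R1": 10.0, "R2": 5.0, "R3": 10.0})
    scaled, _ = eflux(chain_model, w, "EX_B")
    assert scaled.reaction("R1").upper_bound == pytest.approx(10.0)
    assert scaled.reaction("R2").upper_bound == pytest.approx(5.0)


def test_eflux_uniform_weights_keep_bounds(chain_model):
    w = ReactionWeights({"R1": 3.0, "R2": 3.0, "R3": 3.0})
    scaled, _ = eflux(chain_model, w, "EX_B")
    for rid in ("R1", "R2", "R3"):
        assert scaled.reaction(rid).upper_bound == pytest.approx(10.0)


def test_eflux_bottleneck_sets_optimum(chain_model):
    w = ReactionWeights({"R1": 10.0, "R2": 2.0, "R3": 10.0})
    _, sol = eflux(chain_model, w, "EX_B")
    assert sol.objective_value == pytest.approx(2.0)


def test_eflux_zero_vector_stays_feasible(chain_model):
    w = ReactionWeights({"R1": 1.0, "R2": 0.5, "R3": 0.1})
    scaled, _ = eflux(chain_model, w, "EX_B")
    lb, ub = scaled.bounds()
    assert (lb <= 0).all() and (ub >= 0).all()


def test_eflux_errors(chain_model):
    with pytest.raises(ValueError, match="objective"):
        eflux(chain_model, ReactionWeights({"R1": 1.0}), "NOPE")
    with pytest.raises(ValueError, match="zero"):
        eflux(chain_model, ReactionWeights({"R1": 0.0}), "EX_B")


def test_pipeline_determinism_and_log():
    spec = SimulationSpec(seed=4)
    model, _ = make_toy_model(spec)
    expr, meta, _ = simulate_expression(model, spec)
    ctx1 = build_context_model(model, expr, group="case", group_metadata=meta)
    ctx2 = build_context_model(model, expr, group="case", group_metadata=meta)
    assert set(ctx1.model.reaction_ids) == set(ctx2.model.reaction_ids)
    assert ctx1.eflux_bounds == ctx2.eflux_bounds
    assert ctx1.stage_log["input"] == len(model.reactions)
    assert ctx1.stage_log["final"] == len(ctx1.model.reactions)


def test_pipeline_identical_expression_identical_models():
    spec = SimulationSpec(seed=5, effect_log2fc=0.0)
    model, _ = make_toy_model(spec)
    expr, meta, _ = simulate_expression(model, spec)
    # same samples under two labels
    half = expr.copy()
    ctx_a = build_context_model(model, half, samples=list(expr.columns[:5]))
    ctx_b = build_context_model(model, half, samples=list(expr.columns[:5]))
    assert ctx_a.eflux_bounds == ctx_b.eflux_bounds


def test_pipeline_with_tasks_records_score(chain_model):
    import pandas as pd
    from hepatoflux import MetabolicTask

    expr = pd.DataFrame(
        {"s1": [5.0, 5.0, 5.0, 5.0, 5.0]},
        index=["g1", "g2", "g3", "g4", "g5"],
    )
    tasks = [
        MetabolicTask(id="t", inputs=[("A_e", 0, 10)], outputs=[("B_e", 1e-4, 10)])
    ]
    ctx = build_context_model(chain_model, expr, samples="s1", tasks=tasks,
                              objective="EX_B")
    assert ctx.task_report.occurrence_score == pytest.approx(1.0)
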