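"""Synthetic-data generators: determinism, ground truth, marginals."""

import numpy as np
import pytest
from scipy import stats

from hepatoflux import (
    SimulationSpec,
    fastcc,
    make_cohort_fixture,
    make_toy_model,
    read_model,
    simulate_de_pvalues,
    simulate_expression,
    simulate_serum,
    write_model,
)
from hepatoflux.synth import PUBLISHED_GENOTYPE_MARGINALS, PUBLISHED_STAGE_HISTOGRAM


def test_toy_model_is_flux_consistent_by_construction():
    model, _ = make_toy_model(SimulationSpec(seed=8, n_pathways=3,
                                             reactions_per_pathway=5))
    assert fastcc(model) == set(model.reaction_ids)


def test_injected_dead_ends_are_exactly_the_blocked_set():
    spec = SimulationSpec(seed=9, n_dead_ends=4, chains_per_pathway=1)
    model, truth = make_toy_model(spec)
    kept = fastcc(model)
    assert set(model.reaction_ids) - kept == set(truth.planted_inactive_reactions)
    assert len(truth.planted_inactive_reactions) == 4


def test_sbml_round_trip_preserves_subsystems(tmp_path):
    model, _ = make_toy_model(SimulationSpec(seed=10, n_pathways=3))
    path = tmp_path / "toy.xml"
    write_model(model, path)
    back = read_model(path)
    assert {r.id: r.subsystem for r in back.reactions} == {
        r.id: r.subsystem for r in model.reactions
    }


def test_generators_are_pure_functions_of_spec():
    spec = SimulationSpec(seed=33)
    m1, _ = make_toy_model(spec)
    m2, _ = make_toy_model(spec)
    assert [r.id for r in m1.reactions] == [r.id for r in m2.reactions]
    e1, meta1, _ = simulate_expression(m1, spec)
    e2, _, _ = simulate_expression(m2, spec)
    assert e1.equals(e2)
    d1, _ = simulate_de_pvalues(m1, spec)
    d2, _ = simulate_de_pvalues(m2, spec)
    assert d1.equals(d2)
    s1, _, _ = simulate_serum(spec)
    s2, _, _ = simulate_serum(spec)
    assert s1.equals(s2)


def test_zero_effect_groups_indistinguishable():
    """Effect size 0: case/control gene means agree by KS test."""
    ok = 0
    for seed in range(10):
        spec = SimulationSpec(seed=seed, effect_log2fc=0.0)
        model, _ = make_toy_model(spec)
        expr, meta, _ = simulate_expression(model, spec)
        case = expr[meta.index[meta.group == "case"]].to_numpy().ravel()
        control = expr[meta.index[meta.group == "control"]].to_numpy().ravel()
        _, p = stats.ks_2samp(case, control)
        ok += p > 0.01
    assert ok >= 9


def test_planted_effect_shifts_perturbed_genes():
    spec = SimulationSpec(seed=13)
    model, _ = make_toy_model(spec)
    expr, meta, truth = simulate_expression(model, spec)
    case_cols = meta.index[meta.group == "case"]
    ctrl_cols = meta.index[meta.group == "control"]
    lfc = np.log2(expr[case_cols].mean(axis=1) / expr[ctrl_cols].mean(axis=1))
    planted = lfc.loc[list(truth.perturbed_genes)]
    rest = lfc.drop(list(truth.perturbed_genes))
    assert planted.mean() > 2.0
    assert abs(rest.mean()) < 0.5


def test_de_pvalues_referential_integrity():
    spec = SimulationSpec(seed=14)
    model, _ = make_toy_model(spec)
    from hepatoflux import metabolite_gene_map

    nbh = metabolite_gene_map(model)
    planted = sorted(nbh, key=lambda m: -len(nbh[m]))[0]
    spec2 = SimulationSpec(seed=14, de_planted_metabolites=(planted,))
    de, truth = simulate_de_pvalues(model, spec2)
    assert set(de["gene"]) == set(model.genes)
    assert truth.planted_reporter_metabolites == (planted,)
    assert de["p"].between(0, 1).all()


def test_de_planting_unknown_metabolite_rejected():
    spec = SimulationSpec(seed=1, de_planted_metabolites=("NOPE",))
    model, _ = make_toy_model(SimulationSpec(seed=1))
    with pytest.raises(ValueError):
        simulate_de_pvalues(model, spec)


def test_cohort_fixture_matches_published_marginals():
    df = make_cohort_fixture(seed=77)
    assert len(df) == 206
    hist = df["stage"].value_counts().to_dict()
    assert hist == PUBLISHED_STAGE_HISTOGRAM
    for locus, (counts, n_unknown) in PUBLISHED_GENOTYPE_MARGINALS.items():
        col = df[f"genotype_{locus}"]
        assert col.isna().sum() == n_unknown
        assert col.value_counts().to_dict() == counts


def test_cohort_fixture_seeded():
    assert make_cohort_fixture(seed=5).equals(make_cohort_fixture(seed=5))
    assert not make_cohort_fixture(seed=5).equals(make_cohort_fixture(seed=6))


def test_serum_truth_resolves_and_planted_shift_present():
    spec = SimulationSpec(seed=15)
    table, meta, truth = simulate_serum(spec)
    for met, (grp, shift) in truth.shifted_serum.items():
        assert met in table.index
        in_grp = table.loc[met, meta.index[meta == grp]].mean()
        out_grp = table.loc[met, meta.index[meta != grp]].mean()
        assert np.sign(in_grp - out_grp) == np.sign(shift)


def test_invalid_spec_rejected():
    with pytest.raises(ValueError):
        SimulationSpec(n_pathways=1)
    with pytest.raises(ValueError):
        SimulationSpec(n_patients_per_group=0)
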