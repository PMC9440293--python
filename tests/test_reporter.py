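"""Reporter-metabolite scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hepatoflux import (
    GeneStat,
    MetabolicModel,
    Metabolite,
    Reaction,
    SimulationSpec,
    make_toy_model,
    metabolite_gene_map,
    reporter_scores,
    simulate_de_pvalues,
)


@pytest.fixture
def small_net():
    mets = [
        Metabolite("A", compartment="c"),
        Metabolite("B", compartment="c"),
        Metabolite("atp_c", compartment="c", name="ATP"),
    ]
    rxns = [
        Reaction("R1", {"A": -1.0, "B": 1.0, "atp_c": -1.0}, 0, 10, gpr="g1 and g2"),
        Reaction("R2", {"B": -1.0}, 0, 10, gpr="g3"),
        Reaction("R3", {"A": 1.0}, 0, 10),  # no GPR
    ]
    return MetabolicModel(mets, rxns)


def test_neighborhood_union_of_gpr_genes(small_net):
    nbh = metabolite_gene_map(small_net)
    assert nbh["A"] == {"g1", "g2"}
    assert nbh["B"] == {"g1", "g2", "g3"}


def test_currency_metabolites_excluded(small_net):
    nbh = metabolite_gene_map(small_net)
    assert "atp_c" not in nbh
    nbh2 = metabolite_gene_map(small_net, exclude_currency=False)
    assert nbh2["atp_c"] == {"g1", "g2"}


def test_gprless_metabolite_has_no_entry():
    mets = [Metabolite("X", compartment="c")]
    rxns = [Reaction("R", {"X": 1.0}, 0, 10)]
    assert metabolite_gene_map(MetabolicModel(mets, rxns)) == {}


def test_toy_map_equals_hand_built_adjacency(chain_model):
    nbh = metabolite_gene_map(chain_model)
    assert nbh["A"] == {"g1", "g2", "g3"}
    assert nbh["B"] == {"g2", "g3", "g4", "g5"}
    assert nbh["A_e"] == {"g1"}
    assert nbh["B_e"] == {"g4", "g5"}


def test_worked_three_gene_example(small_net):
    """Neighbor p = {0.01, 0.04, 0.5} -> Z_m = (2.3263+1.7507+0)/sqrt(3)."""
    gs = [GeneStat("g1", 0.01), GeneStat("g2", 0.04), GeneStat("g3", 0.5)]
    res = reporter_scores(small_net, gs, n_background=100, seed=0)
    expected = (stats.norm.isf(0.01) + stats.norm.isf(0.04) + 0.0) / np.sqrt(3)
    assert res.loc["B", "Z_m"] == pytest.approx(expected, abs=1e-4)
    assert expected == pytest.approx(2.354, abs=1e-3)


def test_null_all_half_pvalues(small_net):
    """All gene p = 0.5: every z is 0, backgrounds degenerate to the null."""
    gs = [GeneStat(g, 0.5) for g in ("g1", "g2", "g3")]
    res = reporter_scores(small_net, gs, n_background=1000, seed=1)
    assert (res["Z_corr"].abs() < 0.1).all()
    assert res["p"].between(0.4, 0.6).all()


def test_permutation_invariance(small_net):
    gs1 = [GeneStat("g1", 0.02), GeneStat("g2", 0.3), GeneStat("g3", 0.7)]
    gs2 = list(reversed(gs1))
    r1 = reporter_scores(small_net, gs1, n_background=500, seed=3)
    r2 = reporter_scores(small_net, gs2, n_background=500, seed=3)
    pd.testing.assert_frame_equal(r1, r2)


def test_monotone_in_neighbor_p(small_net):
    lo = reporter_scores(
        small_net, [GeneStat("g1", 0.01), GeneStat("g2", 0.2), GeneStat("g3", 0.5)],
        n_background=500, seed=4,
    )
    hi = reporter_scores(
        small_net, [GeneStat("g1", 0.2), GeneStat("g2", 0.2), GeneStat("g3", 0.5)],
        n_background=500, seed=4,
    )
    assert lo.loc["A", "Z_m"] > hi.loc["A", "Z_m"]


def test_background_moments_match_empirical_for_k1():
    model, _ = make_toy_model(SimulationSpec(seed=6, chains_per_pathway=1))
    rng = np.random.default_rng(0)
    gs = [GeneStat(g, float(p)) for g, p in zip(model.genes,
                                                rng.uniform(0.01, 0.99, len(model.genes)))]
    res = reporter_scores(model, gs, n_background=100_000, seed=5)
    zs = np.array([g.z for g in gs])
    k1 = res[res["k"] == 1]
    if not k1.empty:
        assert k1["mu_k"].iloc[0] == pytest.approx(zs.mean(), abs=0.02)
        assert k1["sigma_k"].iloc[0] == pytest.approx(zs.std(ddof=0), abs=0.02)


def test_seed_determinism(small_net):
    gs = [GeneStat("g1", 0.1), GeneStat("g2", 0.6), GeneStat("g3", 0.3)]
    r1 = reporter_scores(small_net, gs, seed=9)
    r2 = reporter_scores(small_net, gs, seed=9)
    pd.testing.assert_frame_equal(r1, r2)


def test_directional_variant_masks_opposite_sign(small_net):
    gs = [GeneStat("g1", 0.01, +1), GeneStat("g2", 0.01, -1), GeneStat("g3", 0.5, +1)]
    up = reporter_scores(small_net, gs, variant="up", n_background=500, seed=2)
    both = reporter_scores(small_net, gs, variant="all", n_background=500, seed=2)
    # masking the downregulated g2 lowers A's aggregate
    assert up.loc["A", "Z_m"] < both.loc["A", "Z_m"]
    assert up.loc["A", "Z_m"] == pytest.approx(stats.norm.isf(0.01) / np.sqrt(2))


def test_planted_neighborhood_ranks_first():
    spec = SimulationSpec(seed=12)
    model, _ = make_toy_model(spec)
    nbh = metabolite_gene_map(model)
    planted = max(nbh, key=lambda m: len(nbh[m]))
    spec2 = SimulationSpec(seed=12, de_planted_metabolites=(planted,))
    de, truth = simulate_de_pvalues(model, spec2)
    res = reporter_scores(model, de, seed=12)
    assert res.index[0] == planted


def test_invalid_variant_rejected(small_net):
    with pytest.raises(ValueError):
        reporter_scores(small_net, [GeneStat("g1", 0.5)], variant="sideways")
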