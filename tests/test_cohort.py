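"""Cohort stratification and serum statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hepatoflux import (
    PatientRecord,
    SimulationSpec,
    anova_tukey,
    assign_disease_groups,
    assign_variant_groups,
    make_cohort_fixture,
    cohort_records,
    pca_outlier_screen,
    simulate_serum,
)


def _rec(pid, stage, g1="CC", g2="CC", g3="--"):
    return PatientRecord(pid, stage, "NAFL", g1, g2, g3)


def test_published_histogram_gives_published_group_sizes():
    """Stage histogram (38,47,53,54,14) -> strata sizes 85/138/107/68."""
    records = []
    i = 0
    for stage, n in {0: 38, 1: 47, 2: 53, 3: 54, 4: 14}.items():
        for _ in range(n):
            records.append(_rec(f"P{i}", stage))
            i += 1
    _, sizes = assign_disease_groups(records)
    assert sizes == {
        "minimal": 85,
        "mild": 138,
        "clinically_significant": 107,
        "advanced": 68,
    }


def test_all_stage_zero():
    records = [_rec(f"P{i}", 0) for i in range(5)]
    flags, sizes = assign_disease_groups(records)
    assert sizes["minimal"] == sizes["mild"] == 5
    assert sizes["clinically_significant"] == sizes["advanced"] == 0


def test_stage3_in_both_overlapping_groups():
    flags, _ = assign_disease_groups([_rec("P0", 3)])
    assert bool(flags.loc["P0", "clinically_significant"])
    assert bool(flags.loc["P0", "advanced"])
    assert not flags.loc["P0", ["minimal", "mild"]].any()


def test_missing_stage_excluded_with_warning():
    with pytest.warns(UserWarning):
        _, sizes = assign_disease_groups([_rec("P0", 1), _rec("P1", None)])
    assert sizes["minimal"] == 1


@pytest.mark.parametrize(
    "genotypes,expected",
    [
        (("GC", "CC", "--"), "PNPLA3"),
        (("GG", "CC", "--"), "PNPLA3"),
        (("CC", "CT", "--"), "TM6SF2"),
        (("CC", "CC", "-T"), "HSD17B13"),
        (("CC", "CC", "--"), "WT"),
        (("GG", "CT", "--"), "excluded"),  # two risk variants
        ((None, "CC", "--"), "excluded"),  # missing genotype
    ],
)
def test_variant_group_assignment(genotypes, expected):
    r = _rec("P0", 1, *genotypes)
    assert assign_variant_groups([r]).loc["P0"] == expected


def test_unknown_genotype_code_rejected():
    with pytest.raises(ValueError, match="PNPLA3"):
        _rec("P0", 1, g1="XY")


def test_variant_groups_partition_cohort():
    df = make_cohort_fixture(seed=3)
    recs = cohort_records(df)
    vg = assign_variant_groups(recs)
    assert set(vg.unique()) <= {"PNPLA3", "TM6SF2", "HSD17B13", "WT", "excluded"}
    assert len(vg) == len(recs)


def test_anova_degenerate_groups_p_one():
    vals = pd.DataFrame([[1.0, 1.0, 1.0, 1.0]], index=["m"],
                        columns=["a1", "a2", "b1", "b2"])
    groups = pd.Series(["A", "A", "B", "B"], index=vals.columns)
    res = anova_tukey(vals, groups)
    assert res.loc["m", "p"] == 1.0


def test_anova_tukey_matches_textbook_computation():
    """Groups {1,2,3},{2,3,4},{5,6,7} against closed-form F and HSD."""
    g = [np.array([1.0, 2, 3]), np.array([2.0, 3, 4]), np.array([5.0, 6, 7])]
    vals = pd.DataFrame([np.concatenate(g)], index=["m"],
                        columns=[f"s{i}" for i in range(9)])
    groups = pd.Series(["A"] * 3 + ["B"] * 3 + ["C"] * 3, index=vals.columns)
    res = anova_tukey(vals, groups)
    # hand ANOVA: grand mean 3.6667; SSB = 3*[(2-11/3)^2+(3-11/3)^2+(6-11/3)^2]
    means = [a.mean() for a in g]
    grand = np.mean(np.concatenate(g))
    ssb = 3 * sum((m - grand) ** 2 for m in means)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in g)
    f_expected = (ssb / 2) / (ssw / 6)
    p_expected = stats.f.sf(f_expected, 2, 6)
    assert res.loc["m", "F"] == pytest.approx(f_expected, rel=1e-9)
    assert res.loc["m", "p"] == pytest.approx(p_expected, rel=1e-9)
    # Tukey HSD A vs C from the studentized range distribution
    mse = ssw / 6
    q = abs(means[0] - means[2]) / np.sqrt(mse / 3)
    p_ac = stats.studentized_range.sf(q, 3, 6)
    assert res.loc["m", "HSD_A_vs_C"] == pytest.approx(p_ac, rel=1e-4)


def test_tukey_matches_statsmodels():
    """Cross-check pairwise HSD p-values against statsmodels (unequal n)."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    rng = np.random.default_rng(2)
    data = np.concatenate([rng.normal(0, 1, 8), rng.normal(1, 1, 12),
                           rng.normal(3, 1, 10)])
    labels = np.array(["A"] * 8 + ["B"] * 12 + ["C"] * 10)
    vals = pd.DataFrame([data], index=["m"], columns=[f"s{i}" for i in range(30)])
    res = anova_tukey(vals, pd.Series(labels, index=vals.columns))
    sm = pairwise_tukeyhsd(data, labels)
    sm_p = dict(zip([f"HSD_{a}_vs_{b}" for a, b in
                     zip(sm.groupsunique[np.array([0, 0, 1])],
                         sm.groupsunique[np.array([1, 2, 2])])], sm.pvalues))
    for key, pv in sm_p.items():
        assert res.loc["m", key] == pytest.approx(pv, abs=1e-3)


def test_shifted_group_recovered():
    spec = SimulationSpec(seed=21)
    table, meta, truth = simulate_serum(spec)
    res = anova_tukey(table, meta)
    for met, (grp, shift) in truth.shifted_serum.items():
        cols = [c for c in res.columns if c.startswith("HSD_") and grp in c]
        assert (res.loc[met, cols] < 0.05).any()
    assert res.loc["lipid_0", "p"] > 0.001  # background not wildly off


def test_tukey_invariances():
    g = [np.array([1.0, 2, 3, 4]), np.array([3.0, 4, 5]), np.array([6.0, 7, 8])]
    vals = pd.DataFrame([np.concatenate(g)], index=["m"],
                        columns=[f"s{i}" for i in range(10)])
    labels = ["A"] * 4 + ["B"] * 3 + ["C"] * 3
    res1 = anova_tukey(vals, pd.Series(labels, index=vals.columns))
    res2 = anova_tukey(vals + 100.0, pd.Series(labels, index=vals.columns))
    for c in res1.columns[:-1]:
        assert res1.loc["m", c] == pytest.approx(res2.loc["m", c], rel=1e-9)


def test_pca_outlier_flags_extreme_sample(rng):
    X = rng.normal(size=(50, 8))
    X[7] += 10.0
    flags = pca_outlier_screen(pd.DataFrame(X))
    assert bool(flags.iloc[7])


def test_pca_outlier_rate_near_alpha(rng):
    X = rng.normal(size=(300, 10))
    flags = pca_outlier_screen(pd.DataFrame(X), conf=0.95)
    rate = flags.mean()
    # binomial 95% band around 0.05 at n=300
    assert 0.01 <= rate <= 0.10


def test_pca_outlier_duplicates_identical(rng):
    X = rng.normal(size=(20, 5))
    Xdup = np.vstack([X, X])
    flags = pca_outlier_screen(pd.DataFrame(Xdup))
    np.testing.assert_array_equal(flags[:20].to_numpy(), flags[20:].to_numpy())
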