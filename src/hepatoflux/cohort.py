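"""Cohort stratification and serum-metabolite statistics.

Patients are stratified by fibrosis stage into overlapping severity
strata — minimal (F0-1), mild (F0-2), clinically significant (F2-3),
advanced (F3-4) — and, independently, into exclusive carriers of the
PNPLA3 rs738409, TM6SF2 rs58542926 or HSD17B13 rs72613567 risk variants
versus wild type.  Serum metabolite intensities (log2) are screened for
outliers by PCA/Hotelling T2 and tested per metabolite with one-way ANOVA
followed by Tukey's HSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "PatientRecord",
    "DISEASE_GROUPS",
    "assign_disease_groups",
    "assign_variant_groups",
    "anova_tukey",
    "pca_outlier_screen",
]

_PNPLA3 = {"CC", "GC", "GG"}
_TM6SF2 = {"CC", "CT", "TT"}
_HSD17B13 = {"--", "-T", "TT"}

#: stage membership of each (overlapping) severity stratum
DISEASE_GROUPS: dict[str, set[int]] = {
    "minimal": {0, 1},
    "mild": {0, 1, 2},
    "clinically_significant": {2, 3},
    "advanced": {3, 4},
}


@dataclass
class PatientRecord:
    patient_id: str
    fibrosis_stage: int | None
    diagnosis: str = "NAFL"  # NAFL | NASH
    genotype_PNPLA3: str | None = None
    genotype_TM6SF2: str | None = None
    genotype_HSD17B13: str | None = None

    def __post_init__(self) -> None:
        if self.fibrosis_stage is not None and self.fibrosis_stage not in range(5):
            raise ValueError(f"{self.patient_id}: stage {self.fibrosis_stage} out of range")
        for value, alphabet, name in (
            (self.genotype_PNPLA3, _PNPLA3, "PNPLA3"),
            (self.genotype_TM6SF2, _TM6SF2, "TM6SF2"),
            (self.genotype_HSD17B13, _HSD17B13, "HSD17B13"),
        ):
            if value is not None and value not in alphabet:
                raise ValueError(
                    f"{self.patient_id}: unknown {name} genotype {value!r}"
                )


def assign_disease_groups(
    records: list[PatientRecord],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Overlapping severity-group membership flags plus group sizes.

    Patients without a fibrosis stage are excluded with a warning.
    Membership is keyed on stage alone; a stage-3 patient belongs to both
    the clinically-significant and the advanced group.
    """
    usable = [r for r in records if r.fibrosis_stage is not None]
    if len(usable) < len(records):
        warnings.warn(f"excluded {len(records) - len(usable)} records without a stage")
    rows = {
        r.patient_id: {
            g: r.fibrosis_stage in stages for g, stages in DISEASE_GROUPS.items()
        }
        for r in usable
    }
    df = pd.DataFrame.from_dict(rows, orient="index").astype(bool)
    sizes = {g: int(df[g].sum()) for g in DISEASE_GROUPS}
    return df, sizes


def assign_variant_groups(records: list[PatientRecord]) -> pd.Series:
    """Exclusive variant-carrier assignment per patient.

    A patient is assigned to a gene's group iff they carry that gene's
    risk variant and are reference at the other two loci; carriers of
    two or more risk variants and patients with any missing genotype are
    ``excluded``; reference at all three loci is ``WT``.
    """
    out = {}
    for r in records:
        g1, g2, g3 = r.genotype_PNPLA3, r.genotype_TM6SF2, r.genotype_HSD17B13
        if g1 is None or g2 is None or g3 is None:
            out[r.patient_id] = "excluded"
            continue
        carriers = [
            ("PNPLA3", g1 in ("GC", "GG")),
            ("TM6SF2", g2 in ("CT", "TT")),
            ("HSD17B13", g3 in ("-T", "TT")),
        ]
        ncarry = sum(c for _, c in carriers)
        if ncarry == 0:
            out[r.patient_id] = "WT"
        elif ncarry == 1:
            out[r.patient_id] = next(name for name, c in carriers if c)
        else:
            out[r.patient_id] = "excluded"
    return pd.Series(out, name="variant_group")


def anova_tukey(
    values: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-metabolite one-way ANOVA + Tukey HSD across groups.

    ``values`` is metabolites x samples (log2 intensities); ``groups``
    maps sample id -> group label.  Groups with a single sample are
    dropped from that metabolite's test.  Returns a table indexed by
    metabolite with F, p, and one ``HSD_<a>_vs_<b>`` p-value column per
    group pair (Tukey-Kramer for unequal sizes).
    """
    groups = groups.loc[values.columns]
    labels = sorted(groups.unique())
    rows = []
    pair_names = [
        f"HSD_{a}_vs_{b}" for i, a in enumerate(labels) for b in labels[i + 1:]
    ]
    for met, row in values.iterrows():
        samples = [row[groups.index[groups == g]].to_numpy(dtype=float) for g in labels]
        used = [(g, s) for g, s in zip(labels, samples) if s.size >= 2]
        if len(used) < 2:
            warnings.warn(f"{met}: fewer than 2 usable groups; skipped")
            continue
        arrs = [s for _, s in used]
        if all(np.ptp(s) == 0 for s in arrs) and len({s[0] for s in arrs}) == 1:
            f_stat, p = np.nan, 1.0
            hsd_p = {name: 1.0 for name in pair_names}
        else:
            f_stat, p = stats.f_oneway(*arrs)
            if np.isnan(p):
                p = 1.0
            res = stats.tukey_hsd(*arrs)
            hsd_p = {}
            used_labels = [g for g, _ in used]
            for i, a in enumerate(used_labels):
                for j in range(i + 1, len(used_labels)):
                    hsd_p[f"HSD_{a}_vs_{used_labels[j]}"] = float(res.pvalue[i, j])
        rows.append({"metabolite": met, "F": f_stat, "p": p, **hsd_p})
    out = pd.DataFrame(rows).set_index("metabolite")
    hsd_cols = [c for c in out.columns if c.startswith("HSD_")]
    out["any_significant"] = (out[hsd_cols] < alpha).any(axis=1)
    return out


def pca_outlier_screen(
    values: pd.DataFrame | np.ndarray,
    n_components: int = 2,
    conf: float = 0.95,
) -> pd.Series:
    """Hotelling T2 outlier flags on the first PCA components.

    ``values`` is samples x features; data are centered and unit-variance
    scaled, projected on the leading components, and each sample's T2 is
    compared with the F-distribution critical value of the ``conf``
    confidence ellipse.
    """
    idx = values.index if isinstance(values, pd.DataFrame) else None
    X = np.asarray(values, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    a = min(n_components, p, n - 1)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=a, svd_solver="full")
    scores = pca.fit_transform(Xs)
    lam = scores.var(axis=0, ddof=1)
    t2 = (scores**2 / lam).sum(axis=1)
    crit = (
        a * (n - 1) / (n - a) * stats.f.ppf(conf, a, n - a)
    )
    flags = pd.Series(t2 > crit, index=idx, name="outlier")
    return flags
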