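"""Normalized differential flux analysis between two conditions.

Subsystem flux tables from two sampled models are quantile-normalized to
a shared reference distribution, log-transformed, and compared per
subsystem with a Welch two-sample t-test; p-values are Benjamini-Hochberg
adjusted.  Significance tiers follow the convention p.adj < 0.05 -> "**",
p.adj < 0.01 -> "***".
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["quantile_normalize", "bh_adjust", "diff_flux"]

#: guard added before taking logs of subsystem means
LOG_GUARD = 1e-12


def quantile_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization, columns as samples.

    Each column is ranked and its values replaced by the across-column
    mean of the order statistics; ties receive the mean of the reference
    values of their tied ranks.  Idempotent and permutation-equivariant
    over columns.
    """
    if table.isna().any().any():
        raise ValueError("table contains missing values")
    if table.shape[1] < 2:
        warnings.warn("single column: quantile normalization is the identity")
        return table.copy()
    arr = table.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        order = np.argsort(arr[:, j], kind="stable")
        vals = arr[order, j]
        assigned = reference.copy()
        # ties receive the mean of the reference values at their positions
        i = 0
        while i < len(vals):
            k = i
            while k + 1 < len(vals) and vals[k + 1] == vals[i]:
                k += 1
            if k > i:
                assigned[i : k + 1] = assigned[i : k + 1].mean()
            i = k + 1
        out[order, j] = assigned
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def diff_flux(
    case: pd.DataFrame,
    control: pd.DataFrame,
    alpha: float = 0.05,
    normalization: str = "joint",
) -> pd.DataFrame:
    """Differential subsystem flux between case and control sample tables.

    Inputs are subsystems x samples tables (from
    :func:`~hepatoflux.sampling.subsystem_flux`).  The subsystem sets are
    intersected; both tables are quantile-normalized against a shared
    reference (``normalization="within"`` normalizes each group on its
    own; ``"none"`` skips normalization), log-transformed, and
    Welch-tested per subsystem.

    Returns a table with columns: mean_case, mean_control (log scale),
    direction, t, p, p_adj, tier.
    """
    shared = case.index.intersection(control.index)
    if len(shared) < len(case.index) or len(shared) < len(control.index):
        warnings.warn(
            f"subsystem sets differ; using the {len(shared)} shared subsystems"
        )
    case = case.loc[shared]
    control = control.loc[shared]
    if normalization == "joint":
        joint = pd.concat([case, control], axis=1, keys=["case", "control"])
        normed = quantile_normalize(joint)
        case_n = normed["case"]
        control_n = normed["control"]
    elif normalization == "within":
        case_n = quantile_normalize(case)
        control_n = quantile_normalize(control)
    elif normalization == "none":
        case_n, control_n = case, control
    else:
        raise ValueError(f"normalization must be joint|within|none, got {normalization!r}")
    lc = np.log(case_n.to_numpy() + LOG_GUARD)
    lk = np.log(control_n.to_numpy() + LOG_GUARD)
    mean_case = lc.mean(axis=1)
    mean_control = lk.mean(axis=1)
    tstat = np.empty(len(shared))
    pval = np.empty(len(shared))
    for i in range(len(shared)):
        a, b = lc[i], lk[i]
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            if a.mean() == b.mean():
                tstat[i], pval[i] = 0.0, 1.0
            else:
                tstat[i] = np.sign(a.mean() - b.mean()) * np.inf
                pval[i] = 0.0
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        tstat[i], pval[i] = t, p
    padj = bh_adjust(pval)
    direction = np.where(mean_case >= mean_control, "up", "down")
    tier = np.where(padj < 0.01, "***", np.where(padj < alpha, "**", ""))
    return pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_control": mean_control,
            "direction": direction,
            "t": tstat,
            "p": pval,
            "p_adj": padj,
            "tier": tier,
        },
        index=shared,
    )
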