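"""Expression-to-reaction integration and HIGH/MODERATE/LOW discretization.

Gene expression is mapped onto reactions through GPR rules (AND = min,
OR = sum) giving one non-negative weight per reaction.  Reaction weights
are approximately log-normal; reactions are discretized against the mean
+/- k*sd of the log-weight distribution into HIGH / LOW / MODERATE input
sets for iMAT.  Reactions without any gene evidence carry a NO_EVIDENCE
marker and enter iMAT as neutral (MODERATE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .gpr import eval_gpr
from .model import MetabolicModel

__all__ = [
    "Category",
    "CategoryThresholds",
    "ReactionWeights",
    "reaction_weights",
    "categorize",
]


class Category(str, Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    NO_EVIDENCE = "NO_EVIDENCE"


@dataclass
class CategoryThresholds:
    """mu +/- multiplier*sigma of the log-weight distribution."""

    mu: float
    sigma: float
    multiplier: float = 1.0

    @property
    def high_cut(self) -> float:
        return self.mu + self.multiplier * self.sigma

    @property
    def low_cut(self) -> float:
        return self.mu - self.multiplier * self.sigma


class ReactionWeights(dict):
    """Map reaction id -> weight; NO_EVIDENCE reactions map to ``None``."""

    def __init__(self, data: dict[str, float | None], provenance: str = ""):
        super().__init__(data)
        self.provenance = provenance

    def weighted(self) -> dict[str, float]:
        return {k: v for k, v in self.items() if v is not None}


def reaction_weights(
    model: MetabolicModel,
    expression: pd.DataFrame,
    samples: str | list[str] | None = None,
    group_metadata: pd.DataFrame | None = None,
    group: str | None = None,
    or_mode: str = "sum",
    min_gene_coverage: float = 0.5,
    aggregate: str = "mean_expression",
) -> ReactionWeights:
    """Evaluate one weight per reaction from an expression table.

    ``expression`` is genes x samples.  Select either explicit ``samples``
    (a sample id or list) or a ``group`` label resolved through
    ``group_metadata`` (indexed by sample id with a ``group`` column).
    Group weights use the per-gene arithmetic mean across the group's
    samples before GPR evaluation (``aggregate="mean_weights"`` instead
    averages per-sample weights).
    """
    if group is not None:
        if group_metadata is None:
            raise ValueError("group selection requires group_metadata")
        samples = list(group_metadata.index[group_metadata["group"] == group])
        if not samples:
            raise ValueError(f"no samples with group {group!r}")
        provenance = f"group:{group}"
    elif samples is None:
        samples = list(expression.columns)
        provenance = "all-samples"
    else:
        if isinstance(samples, str):
            samples = [samples]
        provenance = ",".join(samples)

    model_genes = set(model.genes)
    present = model_genes & set(expression.index)
    if model_genes and len(present) / len(model_genes) < min_gene_coverage:
        raise ValueError(
            f"only {len(present)}/{len(model_genes)} model genes found in "
            "expression table: gene namespace mismatch"
        )

    sub = expression.loc[list(expression.index), samples]

    def weights_for(values: pd.Series) -> dict[str, float | None]:
        gv = values.to_dict()
        return {r.id: eval_gpr(r.gpr, gv, or_mode=or_mode) for r in model.reactions}

    if aggregate == "mean_expression" or len(samples) == 1:
        out = weights_for(sub.mean(axis=1))
    elif aggregate == "mean_weights":
        per_sample = [weights_for(sub[s]) for s in samples]
        out = {}
        for r in model.reactions:
            vals = [w[r.id] for w in per_sample]
            out[r.id] = None if vals[0] is None else float(np.mean(vals))
    else:
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    return ReactionWeights(out, provenance=provenance)


def categorize(
    weights: ReactionWeights,
    pseudo: float = 1e-8,
    multiplier: float = 1.0,
    exclude_zeros: bool = True,
) -> tuple[dict[str, Category], CategoryThresholds]:
    """Discretize reaction weights into HIGH / MODERATE / LOW.

    Thresholds are mu +/- multiplier*sigma of ``log(w + pseudo)`` over the
    evidence-bearing reactions (zero weights excluded from the fit by
    default, since log(0) would otherwise dominate the moments).
    NO_EVIDENCE reactions are assigned MODERATE so iMAT neither rewards
    nor penalizes them.
    """
    weighted = weights.weighted()
    fit_vals = {k: v for k, v in weighted.items() if (v > 0 or not exclude_zeros)}
    if len(fit_vals) < 3:
        raise ValueError("need at least 3 positive reaction weights")
    logs = np.log(np.array(list(fit_vals.values())) + pseudo)
    mu, sigma = float(np.mean(logs)), float(np.std(logs, ddof=0))
    thr = CategoryThresholds(mu=mu, sigma=sigma, multiplier=multiplier)
    if sigma == 0:
        warnings.warn("all reaction weights equal; every reaction MODERATE")
    cats: dict[str, Category] = {}
    for rid, w in weights.items():
        if w is None:
            cats[rid] = Category.NO_EVIDENCE
            continue
        lw = np.log(w + pseudo)
        if sigma > 0 and lw > thr.high_cut:
            cats[rid] = Category.HIGH
        elif sigma > 0 and lw < thr.low_cut:
            cats[rid] = Category.LOW
        else:
            cats[rid] = Category.MODERATE
    return cats, thr


def categories_to_frame(
    weights: ReactionWeights, categories: dict[str, Category]
) -> pd.DataFrame:
    """Tidy (reaction, weight, category) table for export."""
    return pd.DataFrame(
        {
            "reaction": list(weights.keys()),
            "weight": [weights[r] for r in weights],
            "category": [categories[r].value for r in weights],
        }
    ).set_index("reaction")
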