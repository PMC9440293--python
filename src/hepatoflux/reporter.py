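"""Reporter-metabolite analysis.

Scores each metabolite by the aggregated differential-expression evidence
of its network neighborhood: the genes attached (via GPR) to the
reactions that produce or consume it.  Gene p-values are converted to
z-scores z_g = Phi^-1(1 - p); a metabolite with k neighbor genes gets

    Z_m = (1 / sqrt(k)) * sum_{g in N(m)} z_g,

corrected against a size-matched background (mu_k, sigma_k estimated
from random size-k draws of the scored gene universe):

    Z_corr = (Z_m - mu_k) / sigma_k,   p = 1 - Phi(Z_corr).

Directional variants ("up"/"down") neutralize genes of the opposite
fold-change sign by resetting their z to Phi^-1(0.5) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import MetabolicModel
from .diffflux import bh_adjust

__all__ = ["GeneStat", "metabolite_gene_map", "reporter_scores", "DEFAULT_CURRENCY"]

#: currency metabolites excluded from neighborhoods (matched per-compartment
#: by base id, case-insensitive)
DEFAULT_CURRENCY = frozenset(
    {"h2o", "h", "h+", "atp", "adp", "pi", "nadh", "nad", "nad+", "nadph", "nadp",
     "nadp+"}
)

_P_CLAMP = 1e-15


@dataclass
class GeneStat:
    gene: str
    p: float
    direction: int = 0  # sign of the fold change; 0 = unknown

    @property
    def z(self) -> float:
        return float(stats.norm.isf(np.clip(self.p, _P_CLAMP, 1 - _P_CLAMP)))


def _base_id(met_id: str, compartment: str) -> str:
    """Strip a trailing compartment tag like '_c' or '[c]' for currency matching."""
    mid = met_id.lower()
    for suffix in (f"_{compartment.lower()}", f"[{compartment.lower()}]"):
        if mid.endswith(suffix):
            return mid[: -len(suffix)]
    return mid


def metabolite_gene_map(
    model: MetabolicModel,
    exclude_currency: bool = True,
    currency: frozenset[str] = DEFAULT_CURRENCY,
) -> dict[str, frozenset[str]]:
    """Neighborhood map: metabolite -> union of genes of its reactions.

    Metabolites touched only by GPR-less reactions are excluded (k = 0),
    as are currency metabolites (per compartment) when
    ``exclude_currency``.
    """
    out: dict[str, set[str]] = {}
    currency_ids = set()
    if exclude_currency:
        for m in model.metabolites:
            if _base_id(m.id, m.compartment) in currency or m.name.lower() in currency:
                currency_ids.add(m.id)
    for r in model.reactions:
        genes = r.genes
        if not genes:
            continue
        for met in r.stoichiometry:
            if met in currency_ids:
                continue
            out.setdefault(met, set()).update(genes)
    return {m: frozenset(g) for m, g in out.items()}


def reporter_scores(
    model: MetabolicModel,
    gene_stats: list[GeneStat] | pd.DataFrame,
    variant: str = "all",
    n_background: int = 10_000,
    seed: int = 0,
    exclude_currency: bool = True,
) -> pd.DataFrame:
    """Score metabolites as reporters of transcriptional change.

    ``gene_stats`` may be a list of :class:`GeneStat` or a DataFrame with
    columns gene, p and (for directional variants) direction.  Returns a
    table indexed by metabolite with columns k, Z_m, mu_k, sigma_k,
    Z_corr, p, p_adj, sorted by p_adj then p.
    """
    if variant not in ("all", "up", "down"):
        raise ValueError(f"variant must be all|up|down, got {variant!r}")
    if isinstance(gene_stats, pd.DataFrame):
        gene_stats = [
            GeneStat(str(row.gene), float(row.p), int(getattr(row, "direction", 0)))
            for row in gene_stats.itertuples(index=False)
        ]
    if not gene_stats:
        raise ValueError("no gene statistics supplied")
    zmap: dict[str, float] = {}
    want = {"up": 1, "down": -1}.get(variant)
    for g in gene_stats:
        if want is not None and np.sign(g.direction) != want:
            zmap[g.gene] = 0.0  # z of p = 0.5: neutralized
        else:
            zmap[g.gene] = g.z
    universe = np.array(sorted(zmap))
    zvals = np.array([zmap[g] for g in universe])
    nuniv = universe.size

    neighborhoods = metabolite_gene_map(model, exclude_currency=exclude_currency)
    scored = {
        m: sorted(g & set(universe)) for m, g in neighborhoods.items()
    }
    scored = {m: g for m, g in scored.items() if g}
    if not scored:
        raise ValueError("no metabolite has scored neighbor genes")

    ks = sorted({len(g) for g in scored.values()})
    if max(ks) > nuniv:
        raise ValueError("neighborhood larger than the scored gene universe")
    rng = np.random.default_rng(seed)
    mu_k: dict[int, float] = {}
    sd_k: dict[int, float] = {}
    for k in ks:
        if nuniv * n_background <= 50_000_000:
            # vectorized sampling without replacement: k smallest of a
            # random key per row
            keys = rng.random((n_background, nuniv))
            idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
            draws = zvals[idx].sum(axis=1) / np.sqrt(k)
        else:  # pragma: no cover - genome-scale fallback
            draws = np.empty(n_background)
            for b in range(n_background):
                idx = rng.choice(nuniv, size=k, replace=False)
                draws[b] = zvals[idx].sum() / np.sqrt(k)
        mu_k[k] = float(draws.mean())
        sd_k[k] = float(draws.std(ddof=0))

    rows = []
    for m, genes in scored.items():
        k = len(genes)
        zm = sum(zmap[g] for g in genes) / np.sqrt(k)
        mu, sd = mu_k[k], sd_k[k]
        if sd < 1e-12:
            if abs(zm - mu) < 1e-9:
                zc = 0.0  # exact null: every draw identical
            else:
                raise ValueError(
                    f"degenerate background (sigma_{k} = 0) but Z_m != mu_{k}"
                )
        else:
            zc = (zm - mu) / sd
        rows.append((m, k, zm, mu, sd, zc, float(stats.norm.sf(zc))))
    out = pd.DataFrame(
        rows, columns=["metabolite", "k", "Z_m", "mu_k", "sigma_k", "Z_corr", "p"]
    ).set_index("metabolite")
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["variant"] = variant
    return out.sort_values(["p_adj", "p"])
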