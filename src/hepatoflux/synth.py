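"""Synthetic inputs with known ground truth.

Every input of the pipeline can be generated here as a pure function of a
:class:`SimulationSpec` (seed included): toy compartmentalized metabolic
models with subsystems and GPRs, log-normal expression cohorts with
planted subsystem effects, differential-expression p-value tables with
planted reporter neighborhoods, a cohort table reproducing the published
fibrosis-stage and genotype marginals, and log2 serum intensity tables
with planted group shifts.  The accompanying :class:`GroundTruth` records
what was planted so recovery can be scored.

The toy networks are topological stand-ins (uptake -> chain -> secretion
pathways with cross-links), not realistic hepatocyte biochemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import PatientRecord
from .gpr import parse_gpr
from .model import MetabolicModel, Metabolite, Reaction
from .reporter import metabolite_gene_map

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "make_toy_model",
    "simulate_expression",
    "simulate_de_pvalues",
    "make_cohort_fixture",
    "simulate_serum",
    "PUBLISHED_STAGE_HISTOGRAM",
    "PUBLISHED_GENOTYPE_MARGINALS",
]

#: published fibrosis-stage histogram of the 206-patient cohort
PUBLISHED_STAGE_HISTOGRAM = {0: 38, 1: 47, 2: 53, 3: 54, 4: 14}

#: published genotype marginals: locus -> (counts per genotype, n unknown)
PUBLISHED_GENOTYPE_MARGINALS = {
    "PNPLA3": ({"CC": 75, "GC": 89, "GG": 42}, 0),
    "TM6SF2": ({"CC": 156, "CT": 48, "TT": 2}, 0),
    "HSD17B13": ({"--": 120, "-T": 61, "TT": 7}, 18),
}


@dataclass
class SimulationSpec:
    """Conditions of a synthetic study; defaults are the package's standard
    desk-scale conditions (documented in the methods note)."""

    seed: int = 0
    n_pathways: int = 5
    reactions_per_pathway: int = 6  # chain reactions per route
    chains_per_pathway: int = 3  # loosely coupled parallel routes per subsystem
    reversible_fraction: float = 0.2
    n_dead_ends: int = 0
    bound: float = 10.0
    # expression cohort
    n_patients_per_group: int = 20
    groups: tuple[str, str] = ("case", "control")
    perturbed_subsystems: tuple[str, ...] = ("pathway_1",)
    effect_log2fc: float = 3.0  # planted shift of member-gene log2 means
    base_log_mean: float = 2.0  # natural-log scale
    gene_sd: float = 0.4  # between-gene spread of log means
    noise_sd: float = 0.3  # per-sample log noise
    # reporter inputs
    de_planted_metabolites: tuple[str, ...] = ()
    de_beta_params: tuple[float, float] = (0.5, 20.0)
    # serum
    serum_n_per_group: int = 30
    serum_shift_sd: float = 3.0
    n_serum_background: int = 16

    def __post_init__(self) -> None:
        if self.n_pathways < 2:
            raise ValueError("need at least 2 pathways (subsystems)")
        for name in ("reactions_per_pathway", "n_patients_per_group",
                     "serum_n_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class GroundTruth:
    perturbed_subsystems: tuple[str, ...] = ()
    planted_inactive_reactions: tuple[str, ...] = ()
    planted_reporter_metabolites: tuple[str, ...] = ()
    shifted_serum: dict = field(default_factory=dict)  # metabolite -> (group, shift)
    perturbed_genes: tuple[str, ...] = ()
    seed: int = 0


def _gpr_for(rng: np.random.Generator, genes: list[str]) -> str:
    """A 1-3-gene GPR mixing AND/OR shapes."""
    k = len(genes)
    if k == 1:
        return genes[0]
    if k == 2:
        op = rng.choice(["and", "or"])
        return f"{genes[0]} {op} {genes[1]}"
    shape = rng.integers(0, 3)
    g1, g2, g3 = genes
    if shape == 0:
        return f"({g1} and {g2}) or {g3}"
    if shape == 1:
        return f"({g1} or {g2}) and {g3}"
    return f"{g1} or {g2} or {g3}"


def make_toy_model(spec: SimulationSpec) -> tuple[MetabolicModel, GroundTruth]:
    """Build a toy compartmentalized model.

    Each pathway (= subsystem ``pathway_p``) consists of
    ``chains_per_pathway`` parallel uptake -> transport -> chain ->
    secretion routes (loosely coupled, emulating the internal diversity
    of real subsystems); consecutive pathways are cross-linked at
    mid-chain of their first route.  Every internal reaction carries a
    1-3-gene GPR.  A designated ``lipid_sink`` boundary reaction drains a
    lipid pool fed from pathway 0 and serves as the default FBA
    objective.  Optionally ``n_dead_ends`` dead-end reactions (producing
    a metabolite nothing consumes) are injected; the model is otherwise
    flux-consistent by construction.
    """
    rng = np.random.default_rng(spec.seed)
    B = spec.bound
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    gene_counter = 0

    def new_genes(n: int, pathway: int) -> list[str]:
        nonlocal gene_counter
        out = [f"g{pathway}_{gene_counter + i}" for i in range(n)]
        gene_counter += n
        return out

    R = spec.reactions_per_pathway
    for p in range(spec.n_pathways):
        sub = f"pathway_{p}"
        for k in range(spec.chains_per_pathway):
            # route 0 keeps the plain M{p}_* names; extra routes get an
            # x{k} infix
            tag = f"{p}" if k == 0 else f"{p}x{k}"
            chain = [f"M{tag}_{i}_c" for i in range(R + 1)]
            for mid in chain:
                mets.append(Metabolite(mid, compartment="c"))
            mets.append(Metabolite(f"M{tag}_in_e", compartment="e"))
            mets.append(Metabolite(f"M{tag}_out_e", compartment="e"))
            # boundary exchanges are wide open so that the GPR-bearing
            # internal reactions are the binding constraints of every route
            rxns.append(
                Reaction(f"EX_{tag}_in", {f"M{tag}_in_e": -1.0}, -10 * B, 0.0,
                         "exchange", is_exchange=True)
            )
            rxns.append(
                Reaction(f"EX_{tag}_out", {f"M{tag}_out_e": -1.0}, 0.0, 10 * B,
                         "exchange", is_exchange=True)
            )
            g = new_genes(int(rng.integers(1, 4)), p)
            rxns.append(
                Reaction(f"T{tag}_in", {f"M{tag}_in_e": -1.0, chain[0]: 1.0},
                         0.0, B, sub, gpr=parse_gpr(_gpr_for(rng, g)))
            )
            for i in range(R):
                rev = rng.random() < spec.reversible_fraction
                g = new_genes(int(rng.integers(1, 4)), p)
                rxns.append(
                    Reaction(
                        f"R{tag}_{i}",
                        {chain[i]: -1.0, chain[i + 1]: 1.0},
                        -B if rev else 0.0,
                        B,
                        sub,
                        gpr=parse_gpr(_gpr_for(rng, g)),
                    )
                )
            g = new_genes(int(rng.integers(1, 4)), p)
            rxns.append(
                Reaction(f"T{tag}_out", {chain[R]: -1.0, f"M{tag}_out_e": 1.0},
                         0.0, B, sub, gpr=parse_gpr(_gpr_for(rng, g)))
            )
    # cross-links at mid-chain, assigned to the upstream pathway's subsystem
    mid = R // 2
    for p in range(1, spec.n_pathways):
        g = new_genes(int(rng.integers(1, 4)), p - 1)
        rxns.append(
            Reaction(
                f"X{p - 1}_{p}",
                {f"M{p - 1}_{mid}_c": -1.0, f"M{p}_{mid}_c": 1.0},
                0.0,
                B / 2,
                f"pathway_{p - 1}",
                gpr=parse_gpr(_gpr_for(rng, g)),
            )
        )
    # lipid pool fed from pathway 0 terminus; its sink is the objective
    mets.append(Metabolite("lipid_c", compartment="c"))
    g = new_genes(2, 0)
    rxns.append(
        Reaction("lipid_synth", {f"M0_{R}_c": -1.0, "lipid_c": 1.0}, 0.0, B,
                 "pathway_0", gpr=parse_gpr(_gpr_for(rng, g)))
    )
    rxns.append(
        Reaction("lipid_sink", {"lipid_c": -1.0}, 0.0, 10 * B, "exchange",
                 is_exchange=True)
    )
    dead_ids = []
    for d in range(spec.n_dead_ends):
        p = int(rng.integers(0, spec.n_pathways))
        i = int(rng.integers(0, R))
        mets.append(Metabolite(f"DEAD{d}_c", compartment="c"))
        g = new_genes(1, p)
        rid = f"DEAD{d}"
        dead_ids.append(rid)
        rxns.append(
            Reaction(rid, {f"M{p}_{i}_c": -1.0, f"DEAD{d}_c": 1.0}, 0.0, B,
                     f"pathway_{p}", gpr=parse_gpr(g[0]))
        )
    model = MetabolicModel(mets, rxns, objective_reaction="lipid_sink",
                           id=f"toy_seed{spec.seed}")
    truth = GroundTruth(
        perturbed_subsystems=spec.perturbed_subsystems,
        planted_inactive_reactions=tuple(dead_ids),
        seed=spec.seed,
    )
    return model, truth


def _subsystem_genes(model: MetabolicModel, subsystems: set[str]) -> set[str]:
    out: set[str] = set()
    for r in model.reactions:
        if r.subsystem in subsystems:
            out |= r.genes
    return out


def simulate_expression(
    model: MetabolicModel, spec: SimulationSpec
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Log-normal expression cohort with a planted subsystem effect.

    Gene log-expression is Normal(mu_g, noise_sd) per sample with
    mu_g = base + N(0, gene_sd); genes of the perturbed subsystems get
    mu_g + effect_log2fc*ln(2) in the case group.  Returns (expression
    genes x samples, sample metadata with 'group', ground truth).
    """
    rng = np.random.default_rng(spec.seed + 1)
    genes = list(model.genes)
    mu = spec.base_log_mean + rng.normal(0.0, spec.gene_sd, len(genes))
    perturbed = _subsystem_genes(model, set(spec.perturbed_subsystems))
    shift = np.array(
        [spec.effect_log2fc * np.log(2) if g in perturbed else 0.0 for g in genes]
    )
    case, control = spec.groups
    cols, data, labels = [], [], []
    for g_idx, group in enumerate(spec.groups):
        for i in range(spec.n_patients_per_group):
            sid = f"{group}_{i}"
            cols.append(sid)
            labels.append(group)
            mean = mu + (shift if group == case else 0.0)
            data.append(np.exp(mean + rng.normal(0.0, spec.noise_sd, len(genes))))
    expr = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    meta = pd.DataFrame({"group": labels}, index=cols)
    truth = GroundTruth(
        perturbed_subsystems=spec.perturbed_subsystems,
        perturbed_genes=tuple(sorted(perturbed)),
        seed=spec.seed,
    )
    return expr, meta, truth


def simulate_de_pvalues(
    model: MetabolicModel, spec: SimulationSpec
) -> tuple[pd.DataFrame, GroundTruth]:
    """Gene-level DE p-values with planted reporter neighborhoods.

    Background genes draw p ~ Uniform(0,1) with a random direction; the
    neighbor genes of each planted metabolite draw p ~ Beta(a, b)
    (defaults (0.5, 20): sharply enriched near 0) with direction +1.
    """
    rng = np.random.default_rng(spec.seed + 2)
    nbh = metabolite_gene_map(model)
    planted = list(spec.de_planted_metabolites)
    planted_genes: set[str] = set()
    for m in planted:
        if m not in nbh or not nbh[m]:
            raise ValueError(f"planted metabolite {m!r} has no gene neighborhood")
        planted_genes |= set(nbh[m])
    genes = list(model.genes)
    a, b = spec.de_beta_params
    p = rng.uniform(0.0, 1.0, len(genes))
    direction = rng.choice([-1, 1], len(genes))
    for i, g in enumerate(genes):
        if g in planted_genes:
            p[i] = rng.beta(a, b)
            direction[i] = 1
    table = pd.DataFrame({"gene": genes, "p": p, "direction": direction})
    truth = GroundTruth(
        planted_reporter_metabolites=tuple(planted), seed=spec.seed
    )
    return table, truth


def make_cohort_fixture(seed: int = 0) -> pd.DataFrame:
    """206 synthetic patients matching the published cohort marginals.

    The fibrosis-stage histogram is exactly (38, 47, 53, 54, 14) and each
    genotype locus matches its published marginal (HSD17B13 with 18
    unknowns); the joint stage x genotype assignment is randomized (no
    association planted, since only marginals are published).
    """
    rng = np.random.default_rng(seed)
    stages = np.concatenate(
        [np.full(n, s) for s, n in PUBLISHED_STAGE_HISTOGRAM.items()]
    )
    n = stages.size
    cols = {"stage": rng.permutation(stages)}
    for locus, (counts, n_unknown) in PUBLISHED_GENOTYPE_MARGINALS.items():
        vals = np.concatenate(
            [np.full(c, g, dtype=object) for g, c in counts.items()]
            + [np.full(n_unknown, None, dtype=object)]
        )
        assert vals.size == n
        cols[f"genotype_{locus}"] = rng.permutation(vals)
    # diagnosis carried for realism but not used for group membership
    diagnosis = np.where(cols["stage"] >= 2, "NASH",
                         rng.choice(["NAFL", "NASH"], n))
    df = pd.DataFrame(
        {
            "patient": [f"P{i:03d}" for i in range(n)],
            "stage": cols["stage"],
            "diagnosis": diagnosis,
            "genotype_PNPLA3": cols["genotype_PNPLA3"],
            "genotype_TM6SF2": cols["genotype_TM6SF2"],
            "genotype_HSD17B13": cols["genotype_HSD17B13"],
        }
    ).set_index("patient")
    return df


def cohort_records(df: pd.DataFrame) -> list[PatientRecord]:
    """Convert a cohort table to :class:`PatientRecord` objects."""
    recs = []
    for pid, row in df.iterrows():
        recs.append(
            PatientRecord(
                patient_id=str(pid),
                fibrosis_stage=int(row["stage"]),
                diagnosis=str(row["diagnosis"]),
                genotype_PNPLA3=row["genotype_PNPLA3"],
                genotype_TM6SF2=row["genotype_TM6SF2"],
                genotype_HSD17B13=row["genotype_HSD17B13"],
            )
        )
    return recs


def simulate_serum(
    spec: SimulationSpec,
    planted: dict[str, tuple[str, float]] | None = None,
    groups: tuple[str, ...] = ("minimal", "mild", "advanced"),
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Log2 serum intensity table with planted group shifts.

    ``planted`` maps metabolite -> (group, shift in units of the
    within-group sd).  The default plants a ceramide increase and a
    hexosylceramide decrease in the advanced group, mimicking the
    qualitative serum pattern of progressive fibrosis.  Returns
    (metabolites x samples log2 table, sample -> group, ground truth).
    """
    rng = np.random.default_rng(spec.seed + 3)
    if planted is None:
        planted = {
            "Cer_d18_1_16_0": ("advanced", spec.serum_shift_sd),
            "HexCer_d18_1_16_0": ("advanced", -spec.serum_shift_sd),
        }
    names = list(planted) + [f"lipid_{i}" for i in range(spec.n_serum_background)]
    cols, labels = [], []
    for g in groups:
        for i in range(spec.serum_n_per_group):
            cols.append(f"{g}_{i}")
            labels.append(g)
    base = rng.normal(20.0, 2.0, len(names))  # per-metabolite log2 abundance
    data = np.empty((len(names), len(cols)))
    for j, (c, g) in enumerate(zip(cols, labels)):
        x = base + rng.normal(0.0, 1.0, len(names))
        for i, met in enumerate(names):
            if met in planted and planted[met][0] == g:
                x[i] += planted[met][1]
        data[:, j] = x
    table = pd.DataFrame(data, index=names, columns=cols)
    meta = pd.Series(labels, index=cols, name="group")
    truth = GroundTruth(shifted_serum=dict(planted), seed=spec.seed)
    return table, meta, truth
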