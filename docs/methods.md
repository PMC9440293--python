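# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `hepatoflux`, in the order the pipeline runs.

## Constraint-based model and solvers

A model is a stoichiometric matrix S (metabolites × reactions) with flux
bounds in mmol/gDW/h, subsystem labels and GPR rules.  All analyses work
on the steady-state polytope {v : S·v = 0, lb ≤ v ≤ ub}.  Every LP goes
through scipy's HiGHS bindings with a primal feasibility tolerance of
1e-9; MILPs use `scipy.optimize.milp` with a relative MIP gap of 1e-4.
The measurable-flux cutoff is 1e-6 mmol/gDW/h throughout (task passing,
blocked-reaction detection, sampling filters).  SBML L3 FBC I/O is
delegated to cobrapy (subsystems via the groups package, falling back to
the reaction attribute/notes); a native JSON dialect round-trips every
field exactly and is the format of record for bit-identity checks.
MATLAB `.mat` deposits are not a supported input; models are exchanged
as SBML or JSON only.

## Expression integration

GPR evaluation uses AND = min (a complex is limited by its scarcest
subunit) and OR = sum (isoenzyme capacities add); OR = max is available
behind a flag.  Genes missing from the expression table are imputed as
the smallest positive observed value and a reaction with an empty GPR is
NO_EVIDENCE — a sentinel, never zero.  Group-level weights average
expression per gene across the group's samples *before* GPR evaluation
(flag `aggregate="mean_weights"` reverses the order).

Discretization fits mean μ and sd σ of log(w + 1e-8) over the
evidence-bearing reactions, excluding zero weights (log 0 would dominate
the moments; documented choice).  HIGH iff log w > μ + mσ, LOW iff
< μ − mσ, with multiplier m = 1 by default.  NO_EVIDENCE reactions enter
iMAT as MODERATE so absence of evidence is not treated as evidence of
absence.  The partition is scale-equivariant: rescaling all weights by a
constant shifts μ but not the assignment.

## Contextualization

iMAT maximizes Σ_{i∈HIGH}(y⁺_i + y⁻_i) + Σ_{i∈LOW} x_i subject to
steady state, bounds, and big-M activation constraints
(y⁺ = 1 ⇒ v ≥ ε, y⁻ = 1 ⇒ v ≤ −ε, x = 1 ⇒ v = 0).  The activation
threshold ε defaults to 1.0 mmol/gDW/h and must exceed the flux
tolerance.  Exchange reactions are exempt from LOW-silencing — they
carry no GPR evidence, and silencing them would seal the model.  Only
the MILP objective value is contract-guaranteed; alternative optima may
differ in support, so solver settings are fixed for reproducibility.

Draft extraction keeps (i) reactions active in the iMAT flux state
(|v| ≥ ε − tol), (ii) HIGH reactions with a satisfied indicator, and
(iii) all MODERATE/NO_EVIDENCE reactions; LOW reactions silenced by iMAT
are removed, and FASTCC prunes whatever is left blocked.  Blocked
reactions are removed, never "rectified" — no repair procedure is
attempted.  The extracted model is always flux-consistent (a FASTCC
fixed point), which the suite asserts.

`build_context_model` additionally shields the objective's flux route:
the support of one FBA optimum of the template model is excluded from
LOW-silencing (`protect_objective=True`).  Without this, a low-expressed
but essential synthesis step can sever every route to the objective and
E-Flux has nothing to optimize; shielding one witness route is the
minimal intervention that keeps the objective feasible while leaving all
other silencing decisions to iMAT.

FASTCC is the LP-7/LP-3 scheme (iterative support maximization with sign
flips for reversible reactions), not per-reaction FVA.  The LP-7
auxiliary variables are capped at eps_internal = max(tolerance, 1e-4)
rather than the raw 1e-6: with a cap at solver-noise level the support
LP is numerically fragile, and away from finite bounds the flux cone is
scale-free, so any reaction that can carry 1e-6 can carry 1e-4 in the
models considered here.  Support membership is still judged at
0.9 × tolerance.  The property suite verifies set equality with the
independent FVA oracle on dozens of randomized networks.

Task checking closes all exchange reactions (RAVEN-style convention,
configurable), installs temporary task uptake/sink reactions with the
task's bounds, and maximizes total output production; pass iff the
optimum exceeds the tolerance, inverted for should-fail tasks.  The
model is restored bit-identically afterwards (asserted by serializing
before and after).  Whether currency metabolites should stay open during
tasks is left to the task definitions themselves.

E-Flux rescales both bounds of every evidence-bearing reaction by
w_i / w_max, with w_max taken within the same sample/group (not across
groups); NO_EVIDENCE reactions keep native bounds, so v = 0 always stays
feasible.

## Flux sampling and differential flux

The sampler optimizes random objective vectors: c with i.i.d. components
uniform on [−1, 1] over non-exchange reactions (flag to include
exchanges), one LP per sample, storing the optimal vertex.  It is
deliberately non-uniform (an optimal-vertex ensemble, not hit-and-run)
and needs no metabolic objective.  Infinite bounds are capped at ±1000
mmol/gDW/h before sampling.  Identical (model, n, seed) gives
bit-identical matrices.

Aggregation drops reactions whose |flux| never exceeds 1e-6 across
samples, takes |v| and averages within subsystems per sample, over
subsystem-labeled internal reactions only.  Case and control tables are
quantile-normalized jointly (shared reference distribution; per-group
normalization behind a flag), natural-log-transformed with a 1e-12
guard, and compared per subsystem with a Welch (unequal-variance)
t-test; BH adjustment across subsystems; direction is the sign of the
mean log difference.  Sampling replicates are treated as independent —
they are sampling replicates of a model, not biological replicates, so
significance speaks to the difference between the two *models*.  Rank
normalization is compositional: one strongly inflated subsystem depresses
the normalized values of the others, so "down" calls are relative to the
whole profile.

## Reporter metabolites

A metabolite's neighborhood is the union of genes over the reactions
producing or consuming it; currency metabolites (h2o, h, atp, adp, pi,
nad(h), nadp(h), per compartment) are excluded, as are metabolites with
only GPR-less reactions.  Gene p-values are clamped to [1e-15, 1−1e-15]
before z = Φ⁻¹(1−p).  Directional variants neutralize genes of the
opposite fold-change sign (z := 0, i.e. p = 0.5).  Backgrounds μ_k, σ_k
come from 10,000 random size-k draws (without replacement) of the scored
gene universe, per distinct k, seeded.  When σ_k = 0 *and* Z_m = μ_k the
background is exactly degenerate (e.g. all p = 0.5) and Z_corr is 0 by
construction; σ_k = 0 with Z_m ≠ μ_k is an error.  One-sided
p = 1 − Φ(Z_corr), BH across metabolites.

## PLS-DA and cross-validation

NIPALS PLS2 on column-centered, unit-variance X against centered one-hot
Y, deterministic by initializing each component from the Y column with
maximal variance; constant features are dropped with a warning and the
component count is capped at the effective rank.  The Y-variance
explained per component SS_a feeds
VIP_j = sqrt(p·Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a), which satisfies
Σ_j VIP² = p to machine precision.  Cross-validation uses stratified
k-fold (k = 7 default, reduced with a warning if the smallest class is
smaller), pools test-fold decision scores across folds, and computes
one-vs-rest AUROC per class from the pooled scores (rank statistic);
resubstitution predictions are available by calling
`decision_scores` on the fitted model directly.

## Cohort and serum statistics

Severity strata are keyed on fibrosis stage alone — minimal {0,1}, mild
{0,1,2}, clinically significant {2,3}, advanced {3,4} — and overlap by
design (a stage-3 patient is in both of the last two).  Variant groups
require carriage of exactly one risk variant (PNPLA3 rs738409 G allele,
TM6SF2 rs58542926 T allele, HSD17B13 rs72613567 splice variant) with
reference genotypes at the other two loci; multi-variant carriers and
records with missing genotypes are excluded, all-reference patients are
wild type.  Serum tables are log2 intensities; the outlier screen is
Hotelling T² on the first two PCA components of autoscaled data against
the 95% F-distribution ellipse.  ANOVA is one-way per metabolite with
Tukey HSD (Tukey–Kramer for unequal group sizes, via the studentized
range distribution); groups with one sample are dropped from that
metabolite's test, and an all-constant metabolite records p = 1 rather
than NaN.

## Synthetic data: what it emulates, and what it does not

`make_toy_model` builds compartmentalized networks of P pathways
(= subsystems), each consisting of 3 parallel uptake → chain → secretion
routes with 1–3-gene GPRs per internal reaction, cross-links between
consecutive pathways, a lipid pool with a `lipid_sink` objective, and
optional injected dead-ends (the planted blocked set).  Boundary
exchanges are wide open (10× the internal bound) so the GPR-bearing
internal reactions are the binding constraints — the quantity expression
actually modulates.  Subsystems have several loosely coupled routes
because a single fully coupled chain makes subsystem activity
all-or-nothing in vertex samples, a degenerate caricature of real
subsystems.

Default conditions, chosen once: 5 pathways × 6 chain reactions × 3
routes (~150 reactions), 20 patients/group, gene baseline log-mean 2.0
with between-gene sd 0.4 and per-sample log-noise 0.3 (natural-log
scale), planted expression effect log2FC = 3 on the perturbed
subsystem's genes, reversible fraction 0.2, bound 10 mmol/gDW/h.  DE
tables draw background p ~ Uniform(0,1) and planted-neighborhood
p ~ Beta(0.5, 20) with direction +1.  The cohort fixture reproduces the
published 206-patient fibrosis histogram (38/47/53/54/14) and genotype
marginals exactly, with genotypes assigned independently of stage (the
joint distribution is not published; no association is planted).  Serum
tables plant a +3 sd ceramide shift and a −3 sd hexosylceramide shift in
the advanced group over 30 samples/group, a Gaussian log2 caricature of
progressive-fibrosis serum lipidomics.

Passing on these networks demonstrates algorithmic correctness (oracle
equivalence, calibration, recovery of planted effects), not biological
fidelity: the toys have no mass-balanced biochemistry, no realistic GPR
redundancy structure, no batch effects or library-size artifacts in
expression, and sampling replicates stand in for biological replicates.

## Problem sizes and statistical design of the checks

Oracle equivalence runs on deliberately small instances: iMAT vs
exhaustive enumeration on 25 single-route toys (≤ 40 reactions, 5 HIGH +
5 LOW, enumeration visits indicator assignments in descending
satisfaction count and stops at the first LP-feasible one), FASTCC vs
per-reaction FVA on 50 randomized toys with 1–4 injected dead-ends.
Differential-flux recovery uses 6-pathway models, ×4 bound inflation on
one subsystem and 200 samples/group over 20 seeded replicates, with a
matched null (same model, different sampling seeds); under the complete
null BH controls the family-wise rate at ~5%, so ~1 replicate in 20 with
a false call is within expectation.  The PLS-DA permutation null uses 50
samples/class so the null AUROC standard deviation (~0.05) sits well
inside the [0.35, 0.65] reporting band; class means sit on a simplex
(class k shifted along feature k) because collinear class means are not
one-vs-rest separable by any linear score — a geometric property, not an
implementation limit.

## Known limitations

- One witness route protects the objective; a model whose objective
  requires branching routes under knockouts is not handled.
- No alternative-optimum ensembles for iMAT; support-level conclusions
  should rely on the sampled fluxes, not on the single MILP solution.
- The sampler's vertex ensemble has no uniformity guarantee and none is
  intended; distributional statements are about this ensemble.
- Quantile normalization assumes comparable subsystem-rank profiles
  between conditions; gross model-size differences between case and
  control models are normalized away only at the rank level.
- Personalized (per-patient) contextualization uses per-model
  categorization thresholds; cohort-wide thresholds are a flag.
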