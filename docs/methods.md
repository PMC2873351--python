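# Methods

This note records the modelling assumptions, parameter choices and
numerical decisions behind `thermoflux`, and what the synthetic-data
study does and does not establish.

## The thermodynamic flux program

The core program augments steady-state mass balance S·v = 0 with
second-law constraints. Every reaction is split into non-negative
forward and reverse directed components; a reversible reaction
contributes two directions, each with its own binary Z. The reverse
direction's energy expression is the exact negation of the forward one
(same standard energy, same uncertainty realisation, negated mixing
term), so without uncertainty the two directions can never both be
active — this exclusivity is implied by the constraints rather than
imposed separately, which keeps the program linear.

Per directed reaction j with known thermodynamics:

* v_j ≤ Z_j·vmax_j,
* ΔrG'_j − K_j + K_j·Z_j ≤ 0, with the strict inequality ΔrG' < 0
  realised as ΔrG' ≤ −ε with ε = 1e-6 kcal/mol (MILP solvers need
  closed sets; configurable),
* ΔrG'_j = ΔrG'°_j + s_j + RT·Σ_i n_ij·ln x_i.

Per lumped reaction i with member count N_i: ΔrG'_lump,i − K_i·y_i ≤ 0
and y_i + Σ_j α_ij·Z_j ≤ N_i, so simultaneous activity of all members
forces the lump's energy negative.

**Big-M constants** are computed per directed reaction as
|ΔrG'°| + n_se·se + RT·Σ|n_ij|·max(|ln x_min|, |ln x_max|) + 1 kcal/mol,
not as one global constant: the relaxation is tighter and solves faster,
and the +1 margin guarantees K strictly exceeds any attainable |ΔrG'|.

**Solver.** All LPs and MILPs go through scipy's HiGHS backend
(`linprog` / `milp`) with a relative MIP gap of 1e-9. HiGHS is
deterministic for a fixed problem, which the byte-identical-rerun tests
rely on. The build → solve → extract layering is thin enough that
another MILP backend could be substituted behind `tmfa.py` without
touching callers.

## Thermodynamic data

Reaction standard transformed energies are assembled from metabolite
formation energies, ΔrG'° = Σ n_ij·ΔfG'°_i, in kcal/mol. Standard errors
combine in quadrature, which treats the group-contribution fitting
errors of different metabolites as independent — an acknowledged
approximation of the grouped error structure; a reaction-level table
entry overrides both the value and the error when a better estimate
exists. The per-reaction uncertainty slack (±2 se by default) is likewise
independent across reactions; correlated group errors would couple them.
One visible consequence: with nonzero se, the slacks of a cycle's members
need not cancel, so an energy-zero cycle can admit a small amount of
simultaneous flux within the error band. The variability analysis
defaults to running without uncertainty, which restores exact cycle
exclusion and isolates the effect of metabolite activities.

Constants: R = 1.9859e-3 kcal/(mol·K), T = 298.15 K (RT ≈ 0.592
kcal/mol). Default molar activity range 1e-5 to 0.02 M. Water is
excluded from the mixing term (activity 1); protons are excluded because
the energies are transformed values at fixed pH. All of these are
`ThermoConfig` fields, and every CLI run writes them into its manifest
so no defaulted value is silent.

**Lumped reactions.** For each unknown-energy reaction r not yet
covered, the builder solves min Σw subject to A·w = 0, w_r = 1, w ≥ 0,
where A is the stoichiometric matrix restricted to unknown metabolites
and unknown-energy reactions. A feasible optimum is a minimal positive
combination cancelling every unknown metabolite; coefficients are
rationalised to smallest integers and duplicate member sets deduped, in
lexicographic reaction-id order for determinism. Infeasibility marks r
un-lumpable, and such reactions carry no thermodynamic constraint (they
are listed in the lump report). The LP formulation was chosen over a
greedy elimination because it is provably minimal and handles
non-unit stoichiometry (e.g. A → 2X with X → B needs weights 1 and 2)
without special cases.

## Variability analysis and classification

TVA fixes growth as an equality v_growth = g (a fraction-of-optimum mode
is available) and, for every constrained reaction, minimises and
maximises the forward-direction ΔrG' expression over the mixed-integer
feasible set — two MILP solves per reaction, independent of each other;
output order is always network order. A feasibility pre-check runs
first so an over-ambitious growth value fails with a clear error rather
than 2n failed sub-solves.

Classification thresholds: the near-equilibrium band eps_eq = 2 kcal/mol
and the far-from-equilibrium cut eps_far = 5 kcal/mol. Published
near-equilibrium analyses place the band at a few kcal/mol but no single
canonical value exists, so both are mandatory, manifest-echoed knobs
rather than constants; the classification partition (bottleneck /
regulatory candidate / threshold of regulation / unclassified) is
exhaustive and exclusive for any 0 < eps_eq < eps_far, which a property
test enforces. Reaction ranges are reported for the forward direction;
fixtures plant their operating direction forward, and a reaction forced
to run has its maximum capped at −ε by construction, which cannot change
its label relative to the unforced range.

## Expression validation

Fold changes are handled on the log2 scale and the per-gene range width
is max − min over experiments whose coefficient of variation is
*strictly* below cv_max = 0.2. Multi-gene reactions contribute one width
per gene. The class contrast is tested with a two-sided Wilcoxon
rank-sum test (exact null distribution when min(n) ≤ 8 with no ties,
normal approximation with tie correction otherwise; the method used is
recorded in the output) and a Welch unequal-variance t-test. Exactly
these two global tests are run; no multiple-testing correction is
applied. Degenerate inputs (all widths identical; both variances zero
with equal means) return p = 1 rather than NaN. Exchange coefficients
from isotope-labelling studies are joined onto bottleneck rows as opaque
literature annotations — the package does not compute them.

## What the synthetic data emulates

The generator stands in for a genome-scale reconstruction, its
group-contribution table and a microarray compendium:

* **Networks** (4–18 reactions): linear chains, branches, a six-reaction
  futile-cycle network, chains through an unknown-energy metabolite, and
  a mini-core sketching acetate uptake → TCA-like loop → biomass with an
  electron-carrier pair (Q/QH2) whose reduced form leaves through an
  unconstrained exchange. The carrier is what lets every loop step keep
  a realistic planted energy while the formation-energy bookkeeping
  stays globally consistent. Formation energies are always assigned
  first and reaction energies derived, so the loop law (zero cycle
  energy sums) holds to machine precision by construction.
* **Planted classes.** Mini-core steps were given standard energies that
  put them firmly in one class under the default activity bounds:
  near-zero energies (ACt, ACO, ICDH, SUCD, FUM, MDH) → bottleneck,
  strongly negative first-committed steps (ACS, OAAS, CS) → regulatory
  candidate, intermediate steps (AKGD, METB) → threshold. Margins to the
  class boundaries are ≥ 0.3 kcal/mol, so recovery is not
  threshold-knife-edge.
* **Expression**: per gene × experiment, log2 fold changes drawn from
  N(0, σ²_class) — the planted contrast is dispersion (range width), not
  direction, matching how bottleneck and regulated genes are expected to
  differ. CVs are drawn so a configurable fraction (default 20%) fail
  the filter. Defaults: 10 genes per class, 10 experiments, dispersion
  ratio 3.

Generation is a pure function of (kind, parameters, seed).

What passing on these fixtures does **not** show: performance or
correctness at genome scale (hundreds of metabolites, thousands of
binaries — the MILPs here have at most a few dozen variables); realistic
degree distributions, cofactor coupling or compartmentalisation;
microarray noise structure beyond iid normal fold changes; or the
behaviour of the independent-slack uncertainty approximation against
correlated group errors. The enumeration-oracle agreement is exact but
only feasible on networks with ≤ 12 constrained directions.

## Problem sizes and study design

The validation study uses 25 seeded random networks (3–6 constrained
directions) for the oracle sweep, 200 replicates for the null-uniformity
check of the rank-sum p (its Kolmogorov distance from uniform reflects
the test's conservativeness at n = 10 + 10 as much as sampling noise —
discrete rank statistics are super-uniform under the null), and 100
seeds for the power estimate. These sizes give stable two-digit
estimates while keeping the full study around a minute on one CPU.

## Known limitations

* No nonlinear energy-balance formulation and no loopless-FVA shortcut
  algorithms; cycle elimination comes solely from the binary coupling.
* Lump members are constrained through their forward direction only;
  reversible unknown-energy reactions inside lumps are not fully
  covered.
* Metabolite-activity variability (feasible concentration ranges per
  metabolite) is out of scope.
* SBML import is read-only; there is no SBML export.
* Group decomposition of molecular structures is out of scope: the
  package consumes precomputed formation/reaction energies with
  standard errors.
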