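# thermoflux

Thermodynamics-based metabolic flux analysis for constraint-based models:
mixed-integer second-law constraints on flux balance analysis (TMFA),
thermodynamic variability analysis (TVA) of reaction free-energy ranges,
classification of reactions into **thermodynamic bottlenecks** and
**candidates for regulation**, and validation of those classes against
gene-expression fold-change ranges.

It is written for systems biologists who work with stoichiometric
reconstructions (of organisms such as *Geobacter sulfurreducens* or
*E. coli*) and want to know which reactions a cell can only control by
enzyme-level regulation, and which are pinned near equilibrium by
metabolite concentrations alone.

## The model

Flux balance analysis maximises a cellular objective c·v subject to
steady-state mass balance and bounds:

    max c·v   s.t.   S v = 0,   lb ≤ v ≤ ub

with S the m × n stoichiometric matrix. FBA alone admits futile cycles —
internal loops with net flux but no net mass exchange. TMFA removes them by
coupling each reaction direction's flux to the sign of its transformed Gibbs
energy through a binary Zⱼ:

    vⱼ ≤ Zⱼ·vmax,ⱼ                          (flux only when permitted)
    ΔᵣG'ⱼ − Kⱼ + Kⱼ·Zⱼ ≤ 0                  (Zⱼ = 1 ⇒ ΔᵣG'ⱼ < 0)
    ΔᵣG'ⱼ = ΔᵣG'°ⱼ + sⱼ + RT Σᵢ nᵢⱼ ln xᵢ    (activity correction)

where ln xᵢ are metabolite log-activities within configured bounds, sⱼ is a
bounded slack absorbing the group-contribution standard error (|sⱼ| ≤ 2·seⱼ
by default), and Kⱼ is a per-reaction big-M constant. Reactions touching
metabolites of unknown formation energy are combined into **lumped
reactions** whose net stoichiometry cancels the unknowns; lump binaries yᵢ
enforce that the lump's ΔᵣG' is negative whenever all members are active.
Around any closed internal cycle the ΔᵣG'ⱼ sum to zero exactly, so no binary
assignment can make every step negative — cycles are eliminated while
feasible pathways are untouched.

**TVA** fixes growth at a stated rate and minimises/maximises every
constrained reaction's ΔᵣG' over the feasible set. The resulting interval
[ΔᵣG'_min, ΔᵣG'_max] classifies the reaction (defaults eps_eq = 2,
eps_far = 5 kcal/mol):

| range behaviour | label |
|---|---|
| reaches the ±eps_eq band around zero | bottleneck |
| entirely below −eps_far | regulatory candidate |
| upper end between −eps_far and −eps_eq | threshold of regulation |

Bottlenecks run near equilibrium — tiny concentration shifts can stall or
reverse them, so transcription need not regulate them and their genes should
show narrow expression fold-change ranges across perturbations. Regulatory
candidates can never approach equilibrium within the admissible activity
ranges, so flux control must come from enzyme regulation, and their genes
should show wide ranges. The `expression` module tests that contrast: per
gene it keeps fold changes whose coefficient of variation is < 0.2, takes
the [min, max] range, and compares range widths between classes with a
two-sided Wilcoxon rank-sum test and a Welch t-test.

## Worked example

Generate the bundled mini-core network (acetate uptake feeding a TCA-like
loop with an electron-carrier pair, a biomass drain, and an amino-acid-like
branch) plus a synthetic expression compendium, then run the full pipeline:

```
thermoflux simulate network --kind mini_core --seed 1 --out model
thermoflux simulate expression --genes 6 --experiments 8 --effect 3 --seed 4 --out expr
thermoflux run --model model --thermo model/thermo.tsv \
    --growth-rxn BIO --growth-value 2.0 --out run1 \
    --expression expr/exp1.tsv --expression expr/exp2.tsv \
    --expression expr/exp3.tsv --expression expr/exp4.tsv \
    --expression expr/exp5.tsv --expression expr/exp6.tsv \
    --expression expr/exp7.tsv --expression expr/exp8.tsv
```

prints

```
Thermodynamic variability analysis
  growth fixed at:  2 1/hr (no uncertainty)
  eps_eq=2.0 eps_far=5.0 kcal/mol
  class counts: bottleneck=6, regulatory_candidate=3, threshold_of_regulation=2
  reaction       drG_min   drG_max  label
  ACt             -4.500     0.000  bottleneck
  ACS            -16.500    -7.500  regulatory_candidate
  OAAS           -20.184    -6.683  regulatory_candidate
  CS             -17.684    -5.683  regulatory_candidate
  ACO             -3.000    -0.000  bottleneck
  ICDH           -16.818    -0.000  bottleneck
  AKGD           -25.818    -3.315  threshold_of_regulation
  SUCD           -10.001     8.001  bottleneck
  FUM             -5.400     3.600  bottleneck
  MDH             -7.801    10.201  bottleneck
  METB           -12.500    -3.500  threshold_of_regulation
wilcoxon_rank_sum_two_sided: p=0.02381
welch_t_two_sample: p=0.03561
```

Reading it: at growth fixed to 2.0 1/hr, citrate synthase (CS) can never
come within 5 kcal/mol of equilibrium (ΔᵣG'_max = −5.68), so it is a
regulatory candidate; malate dehydrogenase (MDH) spans zero
([−7.8, +10.2] kcal/mol) and is a bottleneck; AKGD sits on the threshold of
regulation. The expression comparison confirms that genes behind the
regulatory candidates have significantly wider fold-change ranges than
genes behind bottlenecks (Wilcoxon p = 0.024, Welch p = 0.036). The run
directory also holds `tva.tsv`, `classes.tsv`, `ranges.tsv`,
`comparison.tsv`, a `manifest.json` pinning every threshold in force, and
`run.log`.

The same objects are available as a library:

```python
from thermoflux import TMFAModel
model = TMFAModel.from_files("model", "model/thermo.tsv")
print(model.fit().summary())                 # optimal fluxes + diagnostics
tva = model.tva("BIO", 2.0)
print(tva.summary())                         # ranges + classes
```

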