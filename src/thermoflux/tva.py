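"""Thermodynamic variability analysis and reaction classification.

TVA fixes growth at a stated value and, for every thermodynamically
constrained reaction, minimises and maximises its activity-corrected
free energy change drG' over the feasible set of the mixed-integer
thermodynamic program — the analogue of flux variability analysis in
energy space. The resulting [drG'_min, drG'_max] interval determines how
a reaction can behave in vivo:

* an interval reaching the near-equilibrium neighbourhood (|drG'| small)
  marks a thermodynamic *bottleneck*: tiny activity perturbations can
  stall or reverse the reaction, so the net flux is concentration-
  controlled and transcriptional regulation is unnecessary;
* a strictly negative interval far from zero marks a *regulatory
  candidate*: no admissible activities bring the reaction near
  equilibrium, so only enzyme-level regulation can modulate its flux;
* an interval whose upper end sits between those two cut-offs is *on the
  threshold of regulation*.

By default the analysis runs without energy uncertainty (slacks pinned
to zero) so the ranges reflect metabolite activities alone.
"""

from __future__ import annotations

from dataclasses import dataclass

from .tmfa import InfeasibleError, TmfaProblem, optimize_expression, solve_tmfa

__all__ = [
    "TvaResult",
    "ReactionClass",
    "run_tva",
    "classify_reactions",
    "compare_class_overlap",
    "write_tva_report",
    "write_class_report",
]

LABELS = ("bottleneck", "regulatory_candidate", "threshold_of_regulation", "unclassified")


@dataclass
class TvaResult:
    reaction_id: str
    drG_min: float
    drG_max: float
    with_uncertainty: bool
    growth_fixed_at: float


@dataclass(frozen=True)
class ReactionClass:
    reaction_id: str
    label: str


def run_tva(
    problem: TmfaProblem,
    growth_reaction: str,
    growth_value: float,
    with_uncertainty: bool = False,
    reactions: list[str] | None = None,
) -> list[TvaResult]:
    """Min/max drG' per constrained reaction at fixed growth.

    Growth is fixed as the equality v_growth = growth_value. Ranges are
    reported for the forward direction of each reaction (the reverse
    expression is the exact negation). Results follow network reaction
    order regardless of any per-reaction solve order.
    """
    prob = problem.with_flux_fixed(growth_reaction, growth_value)
    if not with_uncertainty:
        prob = prob.without_uncertainty()
    feas = solve_tmfa(prob, {growth_reaction: 1.0})
    if feas.status != "optimal":
        raise InfeasibleError(
            f"TMFA infeasible with {growth_reaction} fixed at {growth_value}; "
            "run a plain TMFA feasibility check first"
        )
    wanted = set(reactions) if reactions is not None else None
    results: list[TvaResult] = []
    for rxn in prob.network.reactions:
        if wanted is not None and rxn.id not in wanted:
            continue
        t = prob.thermo_by_id.get(rxn.id)
        if t is None or not (t.known and t.constrained):
            continue
        fwd = next(d for d in prob.directed_for(rxn.id) if d.direction > 0)
        row, const = prob.drg_row(fwd)
        s_lo, lo, _ = optimize_expression(prob, row, const, "min")
        s_hi, hi, _ = optimize_expression(prob, row, const, "max")
        if s_lo != "optimal" or s_hi != "optimal":
            raise InfeasibleError(f"TVA sub-solve failed for {rxn.id} ({s_lo}/{s_hi})")
        results.append(TvaResult(rxn.id, lo, hi, with_uncertainty, growth_value))
    return results


def classify_reactions(
    tva: list[TvaResult], eps_eq: float = 2.0, eps_far: float = 5.0
) -> list[ReactionClass]:
    """Partition reactions by their drG' range (kcal/mol).

    * ``regulatory_candidate``: drG_max < -eps_far (range strictly
      negative, far from equilibrium).
    * ``threshold_of_regulation``: -eps_far <= drG_max < -eps_eq.
    * ``bottleneck``: drG_max >= -eps_eq and drG_min <= +eps_eq (range
      touches the near-equilibrium band or spans zero).
    * ``unclassified``: everything else (strictly positive ranges).

    The partition is exhaustive and exclusive, and invariant to input
    order. Requires 0 < eps_eq < eps_far.
    """
    if not (0 < eps_eq < eps_far):
        raise ValueError("need 0 < eps_eq < eps_far")
    out = []
    for r in tva:
        if r.drG_max < -eps_far:
            label = "regulatory_candidate"
        elif r.drG_max < -eps_eq:
            label = "threshold_of_regulation"
        elif r.drG_min <= eps_eq:
            label = "bottleneck"
        else:
            label = "unclassified"
        out.append(ReactionClass(r.reaction_id, label))
    return out


def compare_class_overlap(
    classes_a: list[ReactionClass], classes_b: list[ReactionClass]
) -> dict[str, dict]:
    """Per-label intersection/union of two classified reaction sets."""
    report: dict[str, dict] = {}
    for label in LABELS:
        a = {c.reaction_id for c in classes_a if c.label == label}
        b = {c.reaction_id for c in classes_b if c.label == label}
        report[label] = {
            "intersection": sorted(a & b),
            "n_intersection": len(a & b),
            "n_union": len(a | b),
            "n_a": len(a),
            "n_b": len(b),
        }
    return report


def write_tva_report(results: list[TvaResult], path, eps_eq=None, eps_far=None) -> None:
    with open(path, "w") as fh:
        if eps_eq is not None:
            fh.write(f"# eps_eq={eps_eq} eps_far={eps_far} kcal/mol\n")
        fh.write("reaction_id\tdrG_min\tdrG_max\twith_uncertainty\tgrowth_fixed_at\n")
        for r in results:
            fh.write(
                f"{r.reaction_id}\t{r.drG_min:.6f}\t{r.drG_max:.6f}\t"
                f"{int(r.with_uncertainty)}\t{r.growth_fixed_at:g}\n"
            )


def read_tva_report(path) -> list[TvaResult]:
    results = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("reaction_id"):
                continue
            rid, lo, hi, unc, growth = line.rstrip("\n").split("\t")
            results.append(TvaResult(rid, float(lo), float(hi), bool(int(unc)), float(growth)))
    return results


def write_class_report(classes: list[ReactionClass], path, eps_eq: float, eps_far: float) -> None:
    with open(path, "w") as fh:
        fh.write(f"# eps_eq={eps_eq} eps_far={eps_far} kcal/mol\n")
        fh.write("reaction_id\tlabel\n")
        for c in classes:
            fh.write(f"{c.reaction_id}\t{c.label}\n")
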