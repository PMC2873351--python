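"""Flux balance analysis and its mixed-integer thermodynamic extension.

The thermodynamic program couples each reaction direction's flux to the
sign of its transformed free energy change through a binary Z:

    (i)   v_d  <=  Z_d * vmax_d                 (flux only when Z_d = 1)
    (ii)  drG'_d - K_d + K_d * Z_d  <=  0       (Z_d = 1 forces drG'_d < 0)
    (iii) drG'_d = drG'0_d + s_r + RT * sum_i n_id * ln x_i
    (iv)  drG'_lump,i - K_i * y_i  <=  0
    (v)   y_i + sum_j alpha_ij * Z_j  <=  N_i   (all members active => y=0)

where s_r is a bounded uncertainty slack (|s_r| <= n_se * se_r), ln x_i
are metabolite log-activities within configured bounds, and K are
per-direction big-M constants just exceeding the largest attainable
|drG'|. Reversible reactions are split into forward/reverse directed
components; the reverse direction's energy expression is the negation of
the forward one (same uncertainty realisation). The strict inequality
drG' < 0 is implemented as drG' <= -eps_thermo.

Solved with scipy's HiGHS backend (LP for FBA, MILP otherwise), which is
deterministic for a fixed problem.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .model_io import MetabolicNetwork
from .thermo import LumpedReaction, ReactionThermo, ThermoConfig

logger = logging.getLogger("thermoflux")

FLUX_TOL = 1e-6


class InfeasibleError(RuntimeError):
    """The optimisation problem has no feasible point."""


@dataclass
class DirectedReaction:
    """One direction of a (possibly reversible) reaction."""

    rxn_id: str
    direction: int  # +1 forward, -1 reverse
    lb: float
    ub: float
    var: int  # flux variable index
    z: int | None = None  # binary index, None when unconstrained
    drG0: float | None = None  # directed standard energy, None if unknown
    big_m: float = 0.0

    @property
    def directed_id(self) -> str:
        return self.rxn_id if self.direction > 0 else self.rxn_id + "_rev"


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded | limit | error
    objective: float
    fluxes: dict[str, float] = field(default_factory=dict)
    ln_activities: dict[str, float] = field(default_factory=dict)
    drG: dict[str, float] = field(default_factory=dict)
    binaries: dict[str, int] = field(default_factory=dict)


@dataclass
class TmfaProblem:
    """Assembled MILP structure over a metabolic network.

    Variable vector layout: [directed fluxes | ln-activities | reaction
    slacks | lump slacks | direction binaries Z | lump binaries y].
    """

    network: MetabolicNetwork
    config: ThermoConfig
    directed: list[DirectedReaction]
    act_index: dict[str, int]  # metabolite id -> ln-activity variable
    slack_index: dict[str, int]  # reaction id -> uncertainty slack variable
    lump_slack_index: dict[str, int]
    lumps: list[LumpedReaction]
    y_index: dict[str, int]  # lump id -> binary variable
    n_var: int
    lb: np.ndarray
    ub: np.ndarray
    integrality: np.ndarray
    constraints: list[LinearConstraint]
    thermo_by_id: dict[str, ReactionThermo]
    unconstrained: list[str]  # reactions with no thermodynamic coverage

    def directed_for(self, rxn_id: str) -> list[DirectedReaction]:
        return [d for d in self.directed if d.rxn_id == rxn_id]

    # -- expression helpers -------------------------------------------------

    def drg_row(self, d: DirectedReaction) -> tuple[np.ndarray, float]:
        """Linear part and constant of drG'_d over the variable vector."""
        row = np.zeros(self.n_var)
        rxn = self.network.reaction(d.rxn_id)
        RT = self.config.RT
        for met, coef in rxn.stoichiometry.items():
            if met in self.act_index:
                row[self.act_index[met]] += d.direction * coef * RT
        if d.rxn_id in self.slack_index:
            row[self.slack_index[d.rxn_id]] += d.direction
        return row, d.direction * self.thermo_by_id[d.rxn_id].drG0

    def lump_drg_row(self, lump: LumpedReaction) -> tuple[np.ndarray, float]:
        row = np.zeros(self.n_var)
        RT = self.config.RT
        for met, coef in lump.net_stoichiometry.items():
            if met in self.act_index:
                row[self.act_index[met]] += coef * RT
        row[self.lump_slack_index[lump.id]] += 1.0
        return row, lump.drG0

    def objective_vector(self, objective) -> np.ndarray:
        """Net-flux objective coefficients expanded to directed variables."""
        coeffs = _objective_map(self.network, objective)
        c = np.zeros(self.n_var)
        for d in self.directed:
            if d.rxn_id in coeffs:
                c[d.var] += d.direction * coeffs[d.rxn_id]
        return c

    def with_flux_fixed(self, rxn_id: str, value: float) -> "TmfaProblem":
        """Copy of the problem with one reaction's net flux pinned."""
        import copy

        prob = copy.deepcopy(self)
        dirs = prob.directed_for(rxn_id)
        if not dirs:
            raise KeyError(rxn_id)
        if value >= 0:
            for d in dirs:
                if d.direction > 0:
                    d.lb = d.ub = value
                else:
                    d.lb = d.ub = 0.0
                prob.lb[d.var], prob.ub[d.var] = d.lb, d.ub
        else:
            for d in dirs:
                if d.direction < 0:
                    d.lb = d.ub = -value
                else:
                    d.lb = d.ub = 0.0
                prob.lb[d.var], prob.ub[d.var] = d.lb, d.ub
        return prob

    def without_uncertainty(self) -> "TmfaProblem":
        """Copy with every uncertainty slack fixed at zero."""
        import copy

        prob = copy.deepcopy(self)
        for idx in list(prob.slack_index.values()) + list(prob.lump_slack_index.values()):
            prob.lb[idx] = prob.ub[idx] = 0.0
        return prob


def _objective_map(network: MetabolicNetwork, objective) -> dict[str, float]:
    if objective is None:
        coeffs = {r.id: r.objective_coeff for r in network.reactions if r.objective_coeff}
        if not coeffs:
            raise ValueError("network carries no objective coefficients")
        return coeffs
    if isinstance(objective, str):
        network.reaction(objective)  # raises KeyError if absent
        return {objective: 1.0}
    return dict(objective)


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------


def solve_fba(network: MetabolicNetwork, objective=None) -> FluxSolution:
    """Maximise c'v subject to S v = 0 and flux bounds (plain LP)."""
    coeffs = _objective_map(network, objective)
    S = network.stoichiometric_matrix()
    n = network.n
    c = np.zeros(n)
    for j, r in enumerate(network.reactions):
        c[j] = coeffs.get(r.id, 0.0)
    bounds = [(r.lower_bound, r.upper_bound) for r in network.reactions]
    res = linprog(-c, A_eq=S, b_eq=np.zeros(network.m), bounds=bounds, method="highs")
    if res.status == 2:
        return FluxSolution(status="infeasible", objective=float("nan"))
    if res.status == 3:
        return FluxSolution(status="unbounded", objective=float("inf"))
    if not res.success:
        return FluxSolution(status="error", objective=float("nan"))
    fluxes = {r.id: float(res.x[j]) for j, r in enumerate(network.reactions)}
    return FluxSolution(status="optimal", objective=float(-res.fun), fluxes=fluxes)


# ---------------------------------------------------------------------------
# TMFA construction
# ---------------------------------------------------------------------------


def build_tmfa(
    network: MetabolicNetwork,
    thermo: list[ReactionThermo],
    lumps: list[LumpedReaction] | None = None,
    config: ThermoConfig | None = None,
    ln_bounds: dict[str, tuple[float, float]] | None = None,
) -> TmfaProblem:
    """Assemble the mixed-integer thermodynamic flux problem.

    ``ln_bounds`` optionally overrides the global ln-activity bounds per
    metabolite. Reactions lacking thermodynamic coverage (unknown energy
    and not in any lump) are logged and left unconstrained.
    """
    config = config or ThermoConfig()
    lumps = lumps or []
    thermo_by_id = {t.reaction_id: t for t in thermo}
    lump_members = {rid for lump in lumps for rid in lump.member_coeffs}

    # directed split
    directed: list[DirectedReaction] = []
    var = 0
    for r in network.reactions:
        if r.upper_bound > 0 or r.lower_bound >= 0:
            directed.append(
                DirectedReaction(r.id, +1, max(r.lower_bound, 0.0), max(r.upper_bound, 0.0), var)
            )
            var += 1
        if r.lower_bound < 0:
            directed.append(
                DirectedReaction(r.id, -1, max(-r.upper_bound, 0.0), -r.lower_bound, var)
            )
            var += 1
    n_flux = var

    def needs_z(d: DirectedReaction) -> bool:
        t = thermo_by_id.get(d.rxn_id)
        if t is None or not t.constrained:
            return False
        if t.known:
            return True
        return d.rxn_id in lump_members and d.direction > 0

    # activity variables for every non-excluded metabolite
    act_index: dict[str, int] = {}
    for m in network.metabolites:
        if m.is_water or (config.exclude_protons and m.is_proton):
            continue
        act_index[m.id] = var
        var += 1

    slack_index: dict[str, int] = {}
    for t in thermo:
        if t.known and t.constrained and t.se > 0:
            slack_index[t.reaction_id] = var
            var += 1
    lump_slack_index: dict[str, int] = {}
    for lump in lumps:
        lump_slack_index[lump.id] = var
        var += 1

    z_dirs = [d for d in directed if needs_z(d)]
    for d in z_dirs:
        d.z = var
        var += 1
    y_index: dict[str, int] = {}
    for lump in lumps:
        y_index[lump.id] = var
        var += 1
    n_var = var

    lb = np.zeros(n_var)
    ub = np.zeros(n_var)
    integrality = np.zeros(n_var)
    for d in directed:
        lb[d.var], ub[d.var] = d.lb, d.ub
    for mid, idx in act_index.items():
        lo, hi = (ln_bounds or {}).get(mid, (config.ln_activity_min, config.ln_activity_max))
        lb[idx], ub[idx] = lo, hi
    for t in thermo:
        if t.reaction_id in slack_index:
            lb[slack_index[t.reaction_id]] = -config.n_se * t.se
            ub[slack_index[t.reaction_id]] = config.n_se * t.se
    for lump in lumps:
        lb[lump_slack_index[lump.id]] = -config.n_se * lump.se
        ub[lump_slack_index[lump.id]] = config.n_se * lump.se
    for d in z_dirs:
        lb[d.z], ub[d.z] = 0.0, 1.0
        integrality[d.z] = 1
    for lump in lumps:
        lb[y_index[lump.id]], ub[y_index[lump.id]] = 0.0, 1.0
        integrality[y_index[lump.id]] = 1

    # big-M per directed reaction / lump
    RT = config.RT
    ln_abs = lambda mid: max(  # noqa: E731
        abs((ln_bounds or {}).get(mid, (config.ln_activity_min, config.ln_activity_max))[0]),
        abs((ln_bounds or {}).get(mid, (config.ln_activity_min, config.ln_activity_max))[1]),
    )
    for d in z_dirs:
        t = thermo_by_id[d.rxn_id]
        if not t.known:
            continue
        rxn = network.reaction(d.rxn_id)
        mix = sum(
            abs(coef) * ln_abs(met)
            for met, coef in rxn.stoichiometry.items()
            if met in act_index
        )
        d.big_m = abs(t.drG0) + config.n_se * t.se + RT * mix + 1.0
        d.drG0 = d.direction * t.drG0

    problem = TmfaProblem(
        network=network,
        config=config,
        directed=directed,
        act_index=act_index,
        slack_index=slack_index,
        lump_slack_index=lump_slack_index,
        lumps=lumps,
        y_index=y_index,
        n_var=n_var,
        lb=lb,
        ub=ub,
        integrality=integrality,
        constraints=[],
        thermo_by_id=thermo_by_id,
        unconstrained=[],
    )

    rows = []
    lbs = []
    ubs = []

    # mass balance over net fluxes
    met_pos = {m.id: i for i, m in enumerate(network.metabolites)}
    mass = np.zeros((network.m, n_var))
    for d in directed:
        rxn = network.reaction(d.rxn_id)
        for met, coef in rxn.stoichiometry.items():
            mass[met_pos[met], d.var] += d.direction * coef
    rows.append(mass)
    lbs.append(np.zeros(network.m))
    ubs.append(np.zeros(network.m))

    eps = config.eps_thermo
    extra_rows = []
    extra_lb = []
    extra_ub = []
    for d in z_dirs:
        # (i) flux-binary link
        row = np.zeros(n_var)
        row[d.var] = 1.0
        row[d.z] = -d.ub
        extra_rows.append(row)
        extra_lb.append(-np.inf)
        extra_ub.append(0.0)
        t = thermo_by_id[d.rxn_id]
        if t.known:
            # (ii)+(iii): drG'_d + (K_d + eps) Z_d <= K_d
            row, const = problem.drg_row(d)
            row = row.copy()
            row[d.z] += d.big_m + eps
            extra_rows.append(row)
            extra_lb.append(-np.inf)
            extra_ub.append(d.big_m - const)
    for lump in lumps:
        row, const = problem.lump_drg_row(lump)
        mix = sum(
            abs(coef) * ln_abs(met)
            for met, coef in lump.net_stoichiometry.items()
            if met in act_index
        )
        big_m = abs(lump.drG0) + config.n_se * lump.se + RT * mix + 1.0
        # (iv): drG'_lump - (K_i + eps) y_i <= -eps
        row = row.copy()
        row[y_index[lump.id]] -= big_m + eps
        extra_rows.append(row)
        extra_lb.append(-np.inf)
        extra_ub.append(-eps - const)
        # (v): y_i + sum_j Z_j <= N_i
        row = np.zeros(n_var)
        row[y_index[lump.id]] = 1.0
        n_members = 0
        for rid in lump.member_coeffs:
            member_dirs = [d for d in directed if d.rxn_id == rid and d.direction > 0]
            if member_dirs and member_dirs[0].z is not None:
                row[member_dirs[0].z] += 1.0
                n_members += 1
        extra_rows.append(row)
        extra_lb.append(-np.inf)
        extra_ub.append(float(n_members))

    if extra_rows:
        rows.append(np.vstack(extra_rows))
        lbs.append(np.array(extra_lb))
        ubs.append(np.array(extra_ub))

    A = np.vstack(rows)
    problem.constraints = [LinearConstraint(A, np.concatenate(lbs), np.concatenate(ubs))]

    problem.unconstrained = sorted(
        t.reaction_id
        for t in thermo
        if t.constrained and not t.known and t.reaction_id not in lump_members
    )
    for rid in problem.unconstrained:
        logger.info("reaction %s has no thermodynamic coverage; left unconstrained", rid)
    return problem


# ---------------------------------------------------------------------------
# TMFA solving
# ---------------------------------------------------------------------------

_MILP_STATUS = {0: "optimal", 1: "limit", 2: "infeasible", 3: "unbounded", 4: "error"}


def _solve_milp(problem: TmfaProblem, c: np.ndarray, sense: int = -1):
    """Minimise sense*c over the problem's feasible set; sense=-1 maximises c."""
    res = milp(
        c=sense * c if sense != 1 else c,
        constraints=problem.constraints,
        bounds=Bounds(problem.lb, problem.ub),
        integrality=problem.integrality,
        options={"mip_rel_gap": 1e-9},
    )
    return res


def _extract(problem: TmfaProblem, x: np.ndarray, objective: float) -> FluxSolution:
    net: dict[str, float] = {}
    for d in problem.directed:
        net[d.rxn_id] = net.get(d.rxn_id, 0.0) + d.direction * float(x[d.var])
    ln_act = {mid: float(x[idx]) for mid, idx in problem.act_index.items()}
    drg = {}
    for d in problem.directed:
        if d.direction > 0 and problem.thermo_by_id.get(d.rxn_id, None) is not None:
            t = problem.thermo_by_id[d.rxn_id]
            if t.known and t.constrained:
                row, const = problem.drg_row(d)
                drg[d.rxn_id] = float(row @ x + const)
    binaries = {
        d.directed_id: int(round(x[d.z])) for d in problem.directed if d.z is not None
    }
    for lump in problem.lumps:
        binaries[lump.id] = int(round(x[problem.y_index[lump.id]]))
    return FluxSolution(
        status="optimal",
        objective=objective,
        fluxes=net,
        ln_activities=ln_act,
        drG=drg,
        binaries=binaries,
    )


def solve_tmfa(problem: TmfaProblem, objective=None) -> FluxSolution:
    """Maximise the (net-flux) objective over the thermodynamic MILP."""
    c = problem.objective_vector(objective)
    res = _solve_milp(problem, c, sense=-1)
    status = _MILP_STATUS.get(res.status, "error")
    if status != "optimal":
        obj = float("inf") if status == "unbounded" else float("nan")
        return FluxSolution(status=status, objective=obj)
    return _extract(problem, res.x, float(c @ res.x))


def optimize_expression(
    problem: TmfaProblem, row: np.ndarray, const: float, sense: str
) -> tuple[str, float, np.ndarray | None]:
    """Min or max a linear expression row.x + const over the feasible set."""
    res = _solve_milp(problem, row, sense=1 if sense == "min" else -1)
    status = _MILP_STATUS.get(res.status, "error")
    if status != "optimal":
        return status, float("nan"), None
    return status, float(row @ res.x + const), res.x


# ---------------------------------------------------------------------------
# flux variability
# ---------------------------------------------------------------------------


def flux_variability(
    source: TmfaProblem | MetabolicNetwork,
    objective=None,
    fix_objective_at: float = 1.0,
    fraction: bool = True,
    reactions: list[str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-reaction [v_min, v_max] with the objective held at (a fraction
    of) its optimum. With a plain network this is classic FVA (LPs); with
    a :class:`TmfaProblem` every sub-solve is a thermodynamic MILP."""
    if isinstance(source, MetabolicNetwork):
        base = solve_fba(source, objective)
        if base.status != "optimal":
            raise InfeasibleError(f"base FBA {base.status}")
        target = fix_objective_at * base.objective if fraction else fix_objective_at
        network = source
        coeffs = _objective_map(network, objective)
        S = network.stoichiometric_matrix()
        n = network.n
        cvec = np.zeros(n)
        for j, r in enumerate(network.reactions):
            cvec[j] = coeffs.get(r.id, 0.0)
        bounds = [(r.lower_bound, r.upper_bound) for r in network.reactions]
        A_ub = -cvec.reshape(1, -1)
        b_ub = np.array([-target + 1e-9])
        out = {}
        targets = reactions or [r.id for r in network.reactions]
        idx = {r.id: j for j, r in enumerate(network.reactions)}
        for rid in targets:
            e = np.zeros(n)
            e[idx[rid]] = 1.0
            lo = linprog(e, A_ub=A_ub, b_ub=b_ub, A_eq=S, b_eq=np.zeros(network.m),
                         bounds=bounds, method="highs")
            hi = linprog(-e, A_ub=A_ub, b_ub=b_ub, A_eq=S, b_eq=np.zeros(network.m),
                         bounds=bounds, method="highs")
            if not (lo.success and hi.success):
                raise InfeasibleError(f"FVA sub-solve failed for {rid}")
            out[rid] = (float(lo.fun), float(-hi.fun))
        return out

    problem = source
    base = solve_tmfa(problem, objective)
    if base.status != "optimal":
        raise InfeasibleError(f"base TMFA {base.status}")
    target = fix_objective_at * base.objective if fraction else fix_objective_at
    c = problem.objective_vector(objective)
    import copy

    prob = copy.deepcopy(problem)
    A = np.vstack([con.A for con in prob.constraints] + [c.reshape(1, -1)])
    lo_all = np.concatenate([con.lb for con in prob.constraints] + [[target - 1e-9]])
    hi_all = np.concatenate([con.ub for con in prob.constraints] + [[np.inf]])
    prob.constraints = [LinearConstraint(A, lo_all, hi_all)]
    targets = reactions or [r.id for r in problem.network.reactions]
    out = {}
    for rid in targets:
        row = np.zeros(prob.n_var)
        for d in prob.directed_for(rid):
            row[d.var] += d.direction
        s_lo, v_lo, _ = optimize_expression(prob, row, 0.0, "min")
        s_hi, v_hi, _ = optimize_expression(prob, row, 0.0, "max")
        if s_lo != "optimal" or s_hi != "optimal":
            raise InfeasibleError(f"TMFA FVA sub-solve failed for {rid}")
        out[rid] = (v_lo, v_hi)
    return out


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def second_law_violations(
    problem: TmfaProblem, solution: FluxSolution, flux_tol: float = FLUX_TOL,
    drg_tol: float = 1e-6,
) -> list[str]:
    """Directed reactions carrying flux whose drG' is not negative."""
    bad = []
    for d in problem.directed:
        t = problem.thermo_by_id.get(d.rxn_id)
        if t is None or not (t.known and t.constrained):
            continue
        v_net = solution.fluxes.get(d.rxn_id, 0.0)
        v_dir = v_net * d.direction
        if v_dir <= flux_tol:
            continue
        drg_fwd = solution.drG.get(d.rxn_id)
        if drg_fwd is None:
            continue
        drg_dir = d.direction * drg_fwd
        if drg_dir > -drg_tol:
            bad.append(d.directed_id)
    return bad


def mass_balance_residual(network: MetabolicNetwork, fluxes: dict[str, float]) -> float:
    S = network.stoichiometric_matrix()
    v = np.array([fluxes.get(r.id, 0.0) for r in network.reactions])
    return float(np.max(np.abs(S @ v))) if network.m else 0.0
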