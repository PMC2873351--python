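"""Reaction-level transformed free energies and lumped reactions.

Standard transformed reaction energies are assembled from metabolite
formation energies, drG'0 = sum_i n_ij * dfG'0_i, with standard errors
combined in quadrature (formation errors treated as independent; a
reaction-level table entry overrides both value and error). The
activity-corrected energy is

    drG' = drG'0 + R*T * sum_i n_ij * ln(x_i)

with water excluded from the mixing term (activity 1) and protons excluded
because the energies are transformed values at fixed pH.

Reactions touching a metabolite of unknown formation energy carry no
energy of their own; positive combinations of such reactions whose net
stoichiometry cancels every unknown metabolite ("lumped reactions") can
still be thermodynamically constrained, and are constructed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .model_io import MetabolicNetwork, Reaction, ThermoTable, UNKNOWN

__all__ = [
    "ThermoConfig",
    "ReactionThermo",
    "LumpedReaction",
    "assemble_reaction_thermo",
    "delta_g_prime",
    "build_lumped_reactions",
]


@dataclass(frozen=True)
class ThermoConfig:
    """Physical constants, activity bounds and uncertainty policy.

    R in kcal/(mol K), T in K; default molar activity range 1e-5 to 0.02 M;
    n_se is the number of standard errors the reaction energy may shift
    (the group-contribution fitting error policy, default 2).
    """

    R: float = 1.9859e-3
    T: float = 298.15
    ln_activity_min: float = math.log(1e-5)
    ln_activity_max: float = math.log(0.02)
    n_se: float = 2.0
    eps_thermo: float = 1e-6  # kcal/mol; strict drG' < 0 as drG' <= -eps
    exclude_protons: bool = True

    def __post_init__(self) -> None:
        if self.ln_activity_min >= self.ln_activity_max:
            raise ValueError("ln_activity_min must be < ln_activity_max")
        if self.n_se < 0:
            raise ValueError("n_se must be >= 0")

    @property
    def RT(self) -> float:
        return self.R * self.T


@dataclass
class ReactionThermo:
    reaction_id: str
    drG0: float  # kcal/mol; NaN when known is False
    se: float
    known: bool
    constrained: bool = True  # False for exchange/biomass reactions


@dataclass
class LumpedReaction:
    """Positive combination of unknown-energy reactions cancelling every
    unknown metabolite, with the energy of its net stoichiometry."""

    id: str
    member_coeffs: dict[str, float]
    net_stoichiometry: dict[str, float]
    drG0: float
    se: float


def _mixing_excluded(network: MetabolicNetwork, met_id: str, config: ThermoConfig) -> bool:
    m = network.metabolite(met_id)
    return m.is_water or (config.exclude_protons and m.is_proton)


def assemble_reaction_thermo(
    network: MetabolicNetwork,
    table: ThermoTable,
    config: ThermoConfig | None = None,
) -> list[ReactionThermo]:
    """Per-reaction drG'0 and se for every reaction, in network order.

    A reaction is ``known`` when all participating non-water, non-proton
    metabolites have formation energies, or a reaction-level override
    exists. Exchange reactions and reactions with a nonzero objective
    coefficient (biomass) are flagged unconstrained.
    """
    config = config or ThermoConfig()
    out: list[ReactionThermo] = []
    for rxn in network.reactions:
        constrained = not rxn.is_exchange and rxn.objective_coeff == 0.0
        if rxn.id in table.reaction_energies:
            value, se = table.reaction_energies[rxn.id]
            out.append(ReactionThermo(rxn.id, value, se, True, constrained))
            continue
        drg = 0.0
        var = 0.0
        known = True
        for met, coef in rxn.stoichiometry.items():
            if _mixing_excluded(network, met, config):
                # water/proton contribute their formation energy if known,
                # but an unknown water/proton never blocks the reaction
                entry = table.formation_energies.get(met, UNKNOWN)
                if entry is not UNKNOWN:
                    value, se = entry
                    drg += coef * value
                    var += (coef * se) ** 2
                continue
            entry = table.formation_energies.get(met, UNKNOWN)
            if entry is UNKNOWN:
                known = False
                break
            value, se = entry
            drg += coef * value
            var += (coef * se) ** 2
        if known:
            out.append(ReactionThermo(rxn.id, drg, math.sqrt(var), True, constrained))
        else:
            out.append(ReactionThermo(rxn.id, float("nan"), 0.0, False, constrained))
    return out


def delta_g_prime(
    thermo: ReactionThermo,
    stoich: dict[str, float],
    ln_activities: dict[str, float],
    config: ThermoConfig,
    network: MetabolicNetwork | None = None,
) -> float:
    """Activity-corrected drG' = drG'0 + RT * sum n_ij ln x_i (kcal/mol).

    Water and (by default) protons are excluded from the mixing sum; every
    other participant must have a ln-activity.
    """
    if not thermo.known:
        raise ValueError(f"reaction {thermo.reaction_id!r} has unknown drG'0")
    mix = 0.0
    for met, coef in stoich.items():
        if network is not None and _mixing_excluded(network, met, config):
            continue
        if met not in ln_activities:
            raise KeyError(f"no ln-activity for metabolite {met!r}")
        mix += coef * ln_activities[met]
    return thermo.drG0 + config.RT * mix


# ---------------------------------------------------------------------------
# lumped reactions
# ---------------------------------------------------------------------------


def _rationalize(weights: np.ndarray, max_den: int = 1000) -> list[Fraction]:
    fracs = [Fraction(w).limit_denominator(max_den) for w in weights]
    from math import lcm

    denominator = lcm(*(f.denominator for f in fracs)) if fracs else 1
    ints = [f * denominator for f in fracs]
    from math import gcd

    g = 0
    for f in ints:
        g = gcd(g, f.numerator)
    if g > 1:
        ints = [f / g for f in ints]
    return ints


def build_lumped_reactions(
    network: MetabolicNetwork,
    thermo: list[ReactionThermo],
    table: ThermoTable,
    config: ThermoConfig | None = None,
) -> tuple[list[LumpedReaction], list[str]]:
    """Construct lumps cancelling unknown-energy metabolites.

    For each unknown-energy reaction r (lexicographic id order) not yet in
    a lump, solve the linear program

        min sum(w)  s.t.  A w = 0,  w_r = 1,  w >= 0

    where A restricts the stoichiometric matrix to unknown metabolites and
    unknown-energy reactions. A feasible minimal combination becomes a
    lump (coefficients rationalised to smallest integers, duplicate member
    sets deduped); infeasibility marks r un-lumpable. Returns
    (lumps, un_lumpable reaction ids).
    """
    from scipy.optimize import linprog

    config = config or ThermoConfig()
    known = {t.reaction_id: t.known for t in thermo}
    unknown_rxns = sorted(
        r.id for r in network.reactions if not known[r.id]
    )
    if not unknown_rxns:
        return [], []
    unknown_mets = sorted(
        m.id
        for m in network.metabolites
        if table.is_unknown(m.id) and not (m.is_water or m.is_proton)
    )
    rxn_by_id = {r.id: r for r in network.reactions}
    A = np.zeros((len(unknown_mets), len(unknown_rxns)))
    met_idx = {m: i for i, m in enumerate(unknown_mets)}
    for j, rid in enumerate(unknown_rxns):
        for met, coef in rxn_by_id[rid].stoichiometry.items():
            if met in met_idx:
                A[met_idx[met], j] = coef

    lumps: list[LumpedReaction] = []
    seen_supports: set[frozenset[str]] = set()
    covered: set[str] = set()
    un_lumpable: list[str] = []
    for rid in unknown_rxns:
        if rid in covered:
            continue
        j0 = unknown_rxns.index(rid)
        nvar = len(unknown_rxns)
        bounds = [(0.0, None)] * nvar
        bounds[j0] = (1.0, 1.0)
        res = linprog(
            c=np.ones(nvar),
            A_eq=A,
            b_eq=np.zeros(len(unknown_mets)),
            bounds=bounds,
            method="highs",
        )
        if not res.success:
            un_lumpable.append(rid)
            continue
        w = np.where(res.x > 1e-9, res.x, 0.0)
        fracs = _rationalize(w)
        members = {
            unknown_rxns[j]: float(fracs[j])
            for j in range(nvar)
            if fracs[j] != 0
        }
        support = frozenset(members)
        covered |= support
        if support in seen_supports:
            continue
        seen_supports.add(support)
        net: dict[str, float] = {}
        for mid, mult in members.items():
            for met, coef in rxn_by_id[mid].stoichiometry.items():
                net[met] = net.get(met, 0.0) + mult * coef
        net = {met: c for met, c in net.items() if abs(c) > 1e-9}
        # drG'0 of the net stoichiometry from known formation energies
        drg = 0.0
        var = 0.0
        for met, coef in net.items():
            m = network.metabolite(met)
            if m.is_water or (config.exclude_protons and m.is_proton):
                entry = table.formation_energies.get(met, UNKNOWN)
                if entry is not UNKNOWN:
                    value, se = entry
                    drg += coef * value
                    var += (coef * se) ** 2
                continue
            entry = table.formation_energies.get(met, UNKNOWN)
            if entry is UNKNOWN:  # pragma: no cover - cancelled by construction
                raise RuntimeError(f"lump net stoichiometry retains unknown {met!r}")
            value, se = entry
            drg += coef * value
            var += (coef * se) ** 2
        lumps.append(
            LumpedReaction(
                id=f"LUMP_{len(lumps) + 1}",
                member_coeffs=members,
                net_stoichiometry=net,
                drG0=drg,
                se=math.sqrt(var),
            )
        )
    return lumps, un_lumpable


def write_lump_report(lumps: list[LumpedReaction], un_lumpable: list[str], path) -> None:
    from .model_io import format_formula

    with open(path, "w") as fh:
        fh.write("lump_id\tmembers\tnet_formula\tdrG0_kcal_mol\tse_kcal_mol\n")
        for lump in lumps:
            members = ";".join(f"{k}:{v:g}" for k, v in sorted(lump.member_coeffs.items()))
            fh.write(
                f"{lump.id}\t{members}\t{format_formula(lump.net_stoichiometry)}\t"
                f"{lump.drG0:.6f}\t{lump.se:.6f}\n"
            )
        for rid in un_lumpable:
            fh.write(f"UNLUMPABLE\t{rid}\t\t\t\n")
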