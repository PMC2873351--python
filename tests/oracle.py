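"""Independent brute-force oracle for the thermodynamic flux program.

Deliberately separate from the package's MILP builder: it enumerates
every assignment of the direction binaries and solves each as a plain
LP with scipy.linprog, so agreement with the package is a two-route
check, not a tautology. Only usable on small networks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import linprog

from thermoflux.model_io import MetabolicNetwork
from thermoflux.thermo import ThermoConfig


class EnumOracle:
    """Exhaustive binary enumeration + LP over a small network.

    Reversible reactions are split into forward/reverse directions; each
    constrained direction gets a binary. Pattern Z_d = 0 pins the
    directed flux to zero; Z_d = 1 requires the direction's drG'
    (drG0 + slack + RT * sum n ln x) <= -eps.
    """

    def __init__(self, network: MetabolicNetwork, drg0: dict[str, float],
                 se: dict[str, float] | None = None,
                 config: ThermoConfig | None = None,
                 with_uncertainty: bool = False):
        self.net = network
        self.cfg = config or ThermoConfig()
        self.drg0 = drg0
        self.se = se or {}
        self.with_uncertainty = with_uncertainty
        # directions: (rxn_id, sign, lb, ub)
        self.dirs = []
        for r in network.reactions:
            if r.upper_bound > 0 or r.lower_bound >= 0:
                self.dirs.append((r.id, +1, max(r.lower_bound, 0.0), max(r.upper_bound, 0.0)))
            if r.lower_bound < 0:
                self.dirs.append((r.id, -1, max(-r.upper_bound, 0.0), -r.lower_bound))
        self.constrained = [
            i for i, (rid, sign, lo, hi) in enumerate(self.dirs)
            if rid in drg0 and hi > 0
        ]
        self.mets = [m.id for m in network.metabolites]
        self.act_mets = [m.id for m in network.metabolites
                         if not (m.is_water or m.is_proton)]
        # variables: fluxes (len dirs) + ln activities + slacks (per rxn in drg0)
        self.slack_rxns = sorted({rid for rid in drg0 if self.se.get(rid, 0.0) > 0}) \
            if with_uncertainty else []
        self.nf = len(self.dirs)
        self.na = len(self.act_mets)
        self.ns = len(self.slack_rxns)
        self.nv = self.nf + self.na + self.ns

    def _drg_row(self, d_idx: int) -> tuple[np.ndarray, float]:
        rid, sign, _, _ = self.dirs[d_idx]
        rxn = self.net.reaction(rid)
        row = np.zeros(self.nv)
        for met, coef in rxn.stoichiometry.items():
            if met in self.act_mets:
                row[self.nf + self.act_mets.index(met)] = sign * coef * self.cfg.RT
        if rid in self.slack_rxns:
            row[self.nf + self.na + self.slack_rxns.index(rid)] = sign
        return row, sign * self.drg0[rid]

    def _lp(self, pattern: dict[int, int], c: np.ndarray,
            fixed_flux: dict[str, float] | None = None):
        lb = np.zeros(self.nv)
        ub = np.zeros(self.nv)
        for i, (rid, sign, lo, hi) in enumerate(self.dirs):
            lb[i], ub[i] = lo, hi
            if pattern.get(i) == 0:
                lb[i] = ub[i] = 0.0
        for k in range(self.na):
            lb[self.nf + k] = self.cfg.ln_activity_min
            ub[self.nf + k] = self.cfg.ln_activity_max
        for k, rid in enumerate(self.slack_rxns):
            lb[self.nf + self.na + k] = -self.cfg.n_se * self.se[rid]
            ub[self.nf + self.na + k] = self.cfg.n_se * self.se[rid]
        A_eq, b_eq = [], []
        for met in self.mets:
            row = np.zeros(self.nv)
            for i, (rid, sign, _, _) in enumerate(self.dirs):
                coef = self.net.reaction(rid).stoichiometry.get(met, 0.0)
                row[i] = sign * coef
            A_eq.append(row)
            b_eq.append(0.0)
        if fixed_flux:
            for rid, val in fixed_flux.items():
                row = np.zeros(self.nv)
                for i, (r2, sign, _, _) in enumerate(self.dirs):
                    if r2 == rid:
                        row[i] = sign
                A_eq.append(row)
                b_eq.append(val)
        A_ub, b_ub = [], []
        for i in self.constrained:
            if pattern.get(i) == 1:
                row, const = self._drg_row(i)
                A_ub.append(row)
                b_ub.append(-self.cfg.eps_thermo - const)
        res = linprog(c, A_ub=np.array(A_ub) if A_ub else None,
                      b_ub=np.array(b_ub) if b_ub else None,
                      A_eq=np.array(A_eq), b_eq=np.array(b_eq),
                      bounds=list(zip(lb, ub)), method="highs")
        return res

    def _patterns(self):
        for bits in itertools.product([0, 1], repeat=len(self.constrained)):
            yield dict(zip(self.constrained, bits))

    def max_objective(self, objective: dict[str, float],
                      fixed_flux: dict[str, float] | None = None) -> float:
        """Best objective over all binary patterns (-inf if none feasible)."""
        c = np.zeros(self.nv)
        for i, (rid, sign, _, _) in enumerate(self.dirs):
            c[i] = -sign * objective.get(rid, 0.0)
        best = -math.inf
        for pattern in self._patterns():
            res = self._lp(pattern, c, fixed_flux)
            if res.success:
                best = max(best, -res.fun)
        return best

    def drg_range(self, rxn_id: str,
                  fixed_flux: dict[str, float] | None = None) -> tuple[float, float]:
        """Min/max forward drG' over the union of feasible patterns."""
        d_idx = next(i for i, (rid, sign, _, _) in enumerate(self.dirs)
                     if rid == rxn_id and sign > 0)
        row, const = self._drg_row(d_idx)
        lo, hi = math.inf, -math.inf
        for pattern in self._patterns():
            res_lo = self._lp(pattern, row, fixed_flux)
            if res_lo.success:
                lo = min(lo, res_lo.fun + const)
            res_hi = self._lp(pattern, -row, fixed_flux)
            if res_hi.success:
                hi = max(hi, -res_hi.fun + const)
        return lo, hi

    def flux_range(self, rxn_id: str, objective: dict[str, float],
                   target: float) -> tuple[float, float]:
        """Min/max net flux with objective >= target, over all patterns."""
        c = np.zeros(self.nv)
        for i, (rid, sign, _, _) in enumerate(self.dirs):
            c[i] = sign * (1.0 if rid == rxn_id else 0.0)
        obj_row = np.zeros(self.nv)
        for i, (rid, sign, _, _) in enumerate(self.dirs):
            obj_row[i] = sign * objective.get(rid, 0.0)
        lo, hi = math.inf, -math.inf
        for pattern in self._patterns():
            res = self._lp_with_target(pattern, c, obj_row, target)
            if res.success:
                lo = min(lo, res.fun)
            res = self._lp_with_target(pattern, -c, obj_row, target)
            if res.success:
                hi = max(hi, -res.fun)
        return lo, hi

    def _lp_with_target(self, pattern, c, obj_row, target):
        res = self._lp(pattern, c, None)
        # re-solve with the objective floor added as an extra A_ub row;
        # rebuild manually to keep _lp simple
        lb = np.zeros(self.nv)
        ub = np.zeros(self.nv)
        for i, (rid, sign, lo, hi) in enumerate(self.dirs):
            lb[i], ub[i] = lo, hi
            if pattern.get(i) == 0:
                lb[i] = ub[i] = 0.0
        for k in range(self.na):
            lb[self.nf + k] = self.cfg.ln_activity_min
            ub[self.nf + k] = self.cfg.ln_activity_max
        for k, rid in enumerate(self.slack_rxns):
            lb[self.nf + self.na + k] = -self.cfg.n_se * self.se[rid]
            ub[self.nf + self.na + k] = self.cfg.n_se * self.se[rid]
        A_eq, b_eq = [], []
        for met in self.mets:
            row = np.zeros(self.nv)
            for i, (rid, sign, _, _) in enumerate(self.dirs):
                row[i] = sign * self.net.reaction(rid).stoichiometry.get(met, 0.0)
            A_eq.append(row)
            b_eq.append(0.0)
        A_ub = [-obj_row]
        b_ub = [-target + 1e-9]
        for i in self.constrained:
            if pattern.get(i) == 1:
                row, const = self._drg_row(i)
                A_ub.append(row)
                b_ub.append(-self.cfg.eps_thermo - const)
        return linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                       A_eq=np.array(A_eq), b_eq=np.array(b_eq),
                       bounds=list(zip(lb, ub)), method="highs")
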