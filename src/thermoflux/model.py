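"""Model/Results front end over the TMFA machinery.

``TMFAModel`` is built from a network plus a thermodynamic table (the
data); ``fit()`` assembles and solves the mixed-integer program and
returns a ``TMFAResults`` carrying fluxes, free energies, binaries and
diagnostics with a ``summary()`` table. ``tva()`` returns a
``TVAResults`` whose ``classify()`` applies the bottleneck/regulatory
partition. The functional layer (solve_fba, build_tmfa, run_tva, ...)
remains available for callers who want the pieces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model_io import MetabolicNetwork, ThermoTable
from .thermo import (
    LumpedReaction,
    ReactionThermo,
    ThermoConfig,
    assemble_reaction_thermo,
    build_lumped_reactions,
)
from .tmfa import (
    FluxSolution,
    TmfaProblem,
    build_tmfa,
    flux_variability,
    mass_balance_residual,
    second_law_violations,
    solve_fba,
    solve_tmfa,
)
from .tva import ReactionClass, TvaResult, classify_reactions, run_tva

__all__ = ["TMFAModel", "TMFAResults", "TVAResults"]


class TMFAModel:
    """Thermodynamics-constrained flux model over a metabolic network.

    Parameters
    ----------
    network : MetabolicNetwork
    thermo_table : ThermoTable
        Formation energies (and optional reaction-level overrides).
    config : ThermoConfig, optional
        Constants, activity bounds, uncertainty policy.
    """

    def __init__(
        self,
        network: MetabolicNetwork,
        thermo_table: ThermoTable,
        config: ThermoConfig | None = None,
    ):
        self.network = network
        self.thermo_table = thermo_table
        self.config = config or ThermoConfig()
        self.reaction_thermo: list[ReactionThermo] = assemble_reaction_thermo(
            network, thermo_table, self.config
        )
        self.lumps: list[LumpedReaction]
        self.lumps, self.un_lumpable = build_lumped_reactions(
            network, self.reaction_thermo, thermo_table, self.config
        )
        self._problem: TmfaProblem | None = None

    @classmethod
    def from_files(cls, model_path, thermo_path, config=None, format="tsv") -> "TMFAModel":
        from .model_io import read_network, read_thermo_table

        network = read_network(model_path, format=format)
        table, warnings = read_thermo_table(thermo_path, network)
        return cls(network, table, config)

    @property
    def problem(self) -> TmfaProblem:
        if self._problem is None:
            self._problem = build_tmfa(
                self.network, self.reaction_thermo, self.lumps, self.config
            )
        return self._problem

    def fit(self, objective=None, thermodynamic: bool = True) -> "TMFAResults":
        """Solve for the optimal flux state (TMFA by default, FBA if
        ``thermodynamic=False``)."""
        if thermodynamic:
            sol = solve_tmfa(self.problem, objective)
        else:
            sol = solve_fba(self.network, objective)
        return TMFAResults(self, sol, thermodynamic=thermodynamic)

    def tva(
        self,
        growth_reaction: str,
        growth_value: float,
        with_uncertainty: bool = False,
        reactions: list[str] | None = None,
    ) -> "TVAResults":
        results = run_tva(self.problem, growth_reaction, growth_value,
                          with_uncertainty, reactions)
        return TVAResults(self, results)

    def flux_variability(self, objective=None, fix_objective_at=1.0,
                         fraction=True, thermodynamic=True, reactions=None):
        source = self.problem if thermodynamic else self.network
        return flux_variability(source, objective, fix_objective_at, fraction, reactions)


@dataclass
class TMFAResults:
    model: TMFAModel
    solution: FluxSolution
    thermodynamic: bool = True

    @property
    def status(self) -> str:
        return self.solution.status

    @property
    def objective(self) -> float:
        return self.solution.objective

    @property
    def fluxes(self) -> pd.Series:
        return pd.Series(self.solution.fluxes, name="flux")

    @property
    def drG(self) -> pd.Series:
        return pd.Series(self.solution.drG, name="drG")

    def diagnostics(self) -> dict:
        residual = mass_balance_residual(self.model.network, self.solution.fluxes)
        out = {"status": self.status, "mass_balance_residual": residual}
        if self.thermodynamic and self.status == "optimal":
            out["second_law_violations"] = second_law_violations(
                self.model.problem, self.solution
            )
        return out

    def summary(self) -> str:
        diag = self.diagnostics()
        lines = [
            "TMFA results" if self.thermodynamic else "FBA results",
            f"  status:               {self.status}",
            f"  objective:            {self.objective:.6g}",
            f"  mass balance |S v|oo: {diag['mass_balance_residual']:.3g}",
        ]
        if "second_law_violations" in diag:
            lines.append(f"  second-law violations: {len(diag['second_law_violations'])}")
        cfg = self.model.config
        lines.append(
            f"  config: RT={cfg.RT:.4f} kcal/mol, ln x in "
            f"[{cfg.ln_activity_min:.3f}, {cfg.ln_activity_max:.3f}], n_se={cfg.n_se}"
        )
        active = [(r, v) for r, v in sorted(self.solution.fluxes.items()) if abs(v) > 1e-9]
        lines.append(f"  nonzero fluxes ({len(active)}):")
        for rid, v in active:
            drg = self.solution.drG.get(rid)
            drg_s = f"  drG'={drg:+.3f}" if drg is not None else ""
            lines.append(f"    {rid:<12s} v={v:+.4f}{drg_s}")
        return "\n".join(lines)


@dataclass
class TVAResults:
    model: TMFAModel
    results: list[TvaResult]
    classes: list[ReactionClass] = field(default_factory=list)
    eps_eq: float = 2.0
    eps_far: float = 5.0

    def classify(self, eps_eq: float = 2.0, eps_far: float = 5.0) -> list[ReactionClass]:
        self.eps_eq, self.eps_far = eps_eq, eps_far
        self.classes = classify_reactions(self.results, eps_eq, eps_far)
        return self.classes

    def to_frame(self) -> pd.DataFrame:
        if not self.classes:
            self.classify(self.eps_eq, self.eps_far)
        labels = {c.reaction_id: c.label for c in self.classes}
        return pd.DataFrame(
            {
                "reaction_id": [r.reaction_id for r in self.results],
                "drG_min": [r.drG_min for r in self.results],
                "drG_max": [r.drG_max for r in self.results],
                "label": [labels[r.reaction_id] for r in self.results],
            }
        ).set_index("reaction_id")

    def summary(self) -> str:
        df = self.to_frame()
        counts = df["label"].value_counts().to_dict()
        growth = self.results[0].growth_fixed_at if self.results else float("nan")
        unc = self.results[0].with_uncertainty if self.results else False
        lines = [
            "Thermodynamic variability analysis",
            f"  growth fixed at:  {growth:g} 1/hr ({'with' if unc else 'no'} uncertainty)",
            f"  eps_eq={self.eps_eq} eps_far={self.eps_far} kcal/mol",
            "  class counts: "
            + ", ".join(f"{k}={v}" for k, v in sorted(counts.items())),
            f"  {'reaction':<12s} {'drG_min':>9s} {'drG_max':>9s}  label",
        ]
        for rid, row in df.iterrows():
            lines.append(
                f"  {rid:<12s} {row.drG_min:>9.3f} {row.drG_max:>9.3f}  {row.label}"
            )
        return "\n".join(lines)
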