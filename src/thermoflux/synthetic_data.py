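"""Synthetic networks, thermodynamic tables and expression datasets.

Fixtures stand in for a genome-scale reconstruction plus its
group-contribution energy table and microarray compendium. Every network
fixture assigns *formation* energies first and derives reaction energies
from them, so cycle sums of drG'0 vanish identically (loop law) — the
property that makes futile cycles thermodynamically infeasible.

Kinds:

``linear_chain``      uptake -> M0 -> ... -> Mk -> export
``branched``          a chain with a branch point and two exports
``futile_cycle``      a pathway B -> C with the wasteful return C -> B
``unknown_metabolite``a chain through a metabolite of unknown energy,
                      so the flanking reactions must be lumped
``mini_core``         ~18 reactions sketching acetate uptake, a TCA-like
                      loop with electron-carrier reoxidation, biomass,
                      and an amino-acid-like branch; plants all three
                      free-energy classes

Expression fixtures draw log2 fold changes per gene x experiment from a
zero-centred normal whose scale is the class dispersion (the planted
contrast is range *width*, not direction), with CVs drawn so a
configurable fraction of entries fail the < 0.2 filter.

Generation is a pure function of (kind, parameters, seed); seeds are
mandatory, there is no hidden global RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_io import (
    ExpressionDataset,
    Metabolite,
    MetabolicNetwork,
    Reaction,
    ThermoTable,
    UNKNOWN,
)
from .thermo import ThermoConfig

__all__ = ["FixtureSpec", "make_network_fixture", "make_expression_fixture", "random_fixture"]

KINDS = ("linear_chain", "branched", "futile_cycle", "unknown_metabolite", "mini_core")


@dataclass
class FixtureSpec:
    kind: str
    seed: int
    n_reactions: int = 0  # advisory; chain length for linear_chain
    formation_se: float = 0.0
    stoich_factor: int = 1  # unknown_metabolite: coefficient on the unknown

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {KINDS}")


@dataclass
class GroundTruth:
    """What the generator planted, for the test suite to recover."""

    cycle_members: dict[str, float] = field(default_factory=dict)  # rxn -> weight
    unknown_metabolites: list[str] = field(default_factory=list)
    planted_lump: dict[str, float] = field(default_factory=dict)
    expected_classes: dict[str, str] = field(default_factory=dict)
    growth_reaction: str = ""
    growth_value: float = 0.0
    pathway_reaction: str = ""  # the cycle step carrying real throughput
    pathway_flux: float = 0.0


def _expected_label(
    stoich: dict[str, float], drg0: float, config: ThermoConfig,
    excluded: set[str], eps_eq: float = 2.0, eps_far: float = 5.0,
) -> str:
    """Classify from the unconstrained mixing span (generator-side oracle)."""
    mix_max = sum(
        c * (config.ln_activity_max if c > 0 else config.ln_activity_min)
        for m, c in stoich.items() if m not in excluded
    ) * config.RT
    mix_min = sum(
        c * (config.ln_activity_min if c > 0 else config.ln_activity_max)
        for m, c in stoich.items() if m not in excluded
    ) * config.RT
    lo, hi = drg0 + mix_min, drg0 + mix_max
    if hi < -eps_far:
        return "regulatory_candidate"
    if hi < -eps_eq:
        return "threshold_of_regulation"
    if lo <= eps_eq:
        return "bottleneck"
    return "unclassified"


def _table(formation: dict[str, float], se: float, unknown: list[str]) -> ThermoTable:
    entries: dict[str, object] = {m: (g, se) for m, g in formation.items()}
    for m in unknown:
        entries[m] = UNKNOWN
    return ThermoTable(formation_energies=entries)


def make_network_fixture(spec: FixtureSpec) -> tuple[MetabolicNetwork, ThermoTable, GroundTruth]:
    if spec.kind == "linear_chain":
        return _linear_chain(spec)
    if spec.kind == "branched":
        return _branched(spec)
    if spec.kind == "futile_cycle":
        return _futile_cycle(spec)
    if spec.kind == "unknown_metabolite":
        return _unknown_metabolite(spec)
    return _mini_core(spec)


def _mets(ids, compartment="c"):
    return [Metabolite(id=i, compartment=compartment) for i in ids]


def _linear_chain(spec: FixtureSpec):
    rng = np.random.default_rng(spec.seed)
    k = max(spec.n_reactions - 2, 2)  # internal steps
    mets = [f"M{i}" for i in range(k + 1)]
    formation = {mets[0]: 0.0}
    for i in range(1, k + 1):
        formation[mets[i]] = formation[mets[i - 1]] - float(rng.uniform(-3.0, 13.0))
    uptake = float(rng.uniform(1.0, 5.0))
    rxns = [Reaction("EX_in", {mets[0]: 1.0}, 0.0, uptake)]
    config = ThermoConfig()
    gt = GroundTruth(growth_reaction="EX_out", growth_value=uptake)
    for i in range(1, k + 1):
        rid = f"R{i}"
        stoich = {mets[i - 1]: -1.0, mets[i]: 1.0}
        drg0 = formation[mets[i]] - formation[mets[i - 1]]
        rxns.append(Reaction(rid, stoich, 0.0, 100.0))
        gt.expected_classes[rid] = _expected_label(stoich, drg0, config, set())
    rxns.append(Reaction("EX_out", {mets[k]: -1.0}, 0.0, 100.0, objective_coeff=1.0))
    net = MetabolicNetwork(_mets(mets), rxns)
    return net, _table(formation, spec.formation_se, []), gt


def _branched(spec: FixtureSpec):
    rng = np.random.default_rng(spec.seed)
    mets = ["A", "B", "C", "D"]
    formation = {
        "A": 0.0,
        "B": -float(rng.uniform(1.0, 12.0)),
    }
    formation["C"] = formation["B"] - float(rng.uniform(-2.0, 12.0))
    formation["D"] = formation["B"] - float(rng.uniform(-2.0, 12.0))
    uptake = float(rng.uniform(1.0, 5.0))
    config = ThermoConfig()
    rxns = [
        Reaction("EX_A", {"A": 1.0}, 0.0, uptake),
        Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, 100.0),
        Reaction("R2", {"B": -1.0, "C": 1.0}, 0.0, 100.0),
        Reaction("R3", {"B": -1.0, "D": 1.0}, 0.0, 100.0),
        Reaction("EX_C", {"C": -1.0}, 0.0, 100.0, objective_coeff=1.0),
        Reaction("EX_D", {"D": -1.0}, 0.0, 100.0),
    ]
    gt = GroundTruth(growth_reaction="EX_C", growth_value=uptake)
    for rid, (s, p) in {"R1": ("A", "B"), "R2": ("B", "C"), "R3": ("B", "D")}.items():
        gt.expected_classes[rid] = _expected_label(
            {s: -1.0, p: 1.0}, formation[p] - formation[s], config, set()
        )
    net = MetabolicNetwork(_mets(mets), rxns)
    return net, _table(formation, spec.formation_se, []), gt


def _futile_cycle(spec: FixtureSpec):
    """Six reactions: uptake -> A -> B -> C -> D -> export, plus the wasteful
    return C -> B. drG'0(B->C) = -0.5 and drG'0(C->B) = +0.5, so either
    direction alone is admissible within the activity bounds but the closed
    cycle (energy sum exactly zero) can never carry simultaneous flux.
    Fixed topology; the seed only matters for the API's purity contract."""
    formation = {"A": 0.0, "B": -8.0, "C": -8.5, "D": -16.5}
    uptake = 5.0
    rxns = [
        Reaction("EX_A", {"A": 1.0}, 0.0, uptake),
        Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, 100.0),
        Reaction("R2", {"B": -1.0, "C": 1.0}, 0.0, 100.0),
        Reaction("R3", {"C": -1.0, "B": 1.0}, 0.0, 100.0),
        Reaction("R4", {"C": -1.0, "D": 1.0}, 0.0, 100.0),
        Reaction("EX_D", {"D": -1.0}, 0.0, 100.0, objective_coeff=1.0),
    ]
    net = MetabolicNetwork(_mets(["A", "B", "C", "D"]), rxns)
    gt = GroundTruth(
        cycle_members={"R2": 1.0, "R3": 1.0},
        growth_reaction="EX_D",
        growth_value=uptake,
        pathway_reaction="R2",
        pathway_flux=uptake,
    )
    config = ThermoConfig()
    for rid in ("R1", "R2", "R3", "R4"):
        rxn = next(r for r in rxns if r.id == rid)
        drg0 = sum(c * formation[m] for m, c in rxn.stoichiometry.items())
        gt.expected_classes[rid] = _expected_label(rxn.stoichiometry, drg0, config, set())
    return net, _table(formation, spec.formation_se, []), gt


def _unknown_metabolite(spec: FixtureSpec):
    f = max(int(spec.stoich_factor), 1)
    formation = {"A": 0.0, "B": -12.0 / f}
    rxns = [
        Reaction("EX_A", {"A": 1.0}, 0.0, 5.0),
        Reaction("R1", {"A": -1.0, "X": float(f)}, 0.0, 100.0),
        Reaction("R2", {"X": -1.0, "B": 1.0}, 0.0, 100.0),
        Reaction("EX_B", {"B": -1.0}, 0.0, 100.0, objective_coeff=1.0),
    ]
    net = MetabolicNetwork(_mets(["A", "X", "B"]), rxns)
    gt = GroundTruth(
        unknown_metabolites=["X"],
        planted_lump={"R1": 1.0, "R2": float(f)},
        growth_reaction="EX_B",
        growth_value=5.0 * f,
    )
    return net, _table(formation, spec.formation_se, ["X"]), gt


# mini_core formation energies (kcal/mol). The TCA-like loop closes on a
# Q/QH2 electron-carrier pair whose reduced form leaves through an
# unconstrained exchange, so each loop step keeps its planted class while
# the formation-energy bookkeeping stays globally consistent.
_MINI_FORMATION = {
    "ac_e": 0.0,
    "ac": 0.0,
    "accoa": -12.0,
    "co2": 0.0,
    "q": 0.0,
    "qh2": -10.175,
    "oaa": -18.0,
    "cit": -47.0,
    "icit": -45.5,
    "akg": -37.825,
    "succ": -37.65,
    "fum": -28.475,
    "mal": -29.375,
    "metx": -45.825,
    "bm": 0.0,
}

# GPR gene names follow the expression generator's class-prefixed scheme
# (reg_g*/bot_g*/thr_g*), so a generated expression fixture joins onto the
# planted classes without any renaming.
_MINI_REACTIONS = [
    # (id, stoichiometry, lb, ub, objective, gpr)
    ("EX_ac", {"ac_e": 1.0}, 0.0, 5.0, 0.0, ""),
    ("ACt", {"ac_e": -1.0, "ac": 1.0}, 0.0, 100.0, 0.0, "bot_g1"),
    ("ACS", {"ac": -1.0, "accoa": 1.0}, 0.0, 100.0, 0.0, "reg_g1"),
    ("OAAS", {"ac": -1.0, "co2": -1.0, "oaa": 1.0}, 0.0, 100.0, 0.0, "reg_g2"),
    ("CS", {"accoa": -1.0, "oaa": -1.0, "cit": 1.0}, 0.0, 100.0, 0.0, "reg_g3"),
    ("ACO", {"cit": -1.0, "icit": 1.0}, 0.0, 100.0, 0.0, "bot_g2"),
    ("ICDH", {"icit": -1.0, "q": -1.0, "akg": 1.0, "co2": 1.0, "qh2": 1.0},
     0.0, 100.0, 0.0, "bot_g3"),
    ("AKGD", {"akg": -1.0, "q": -1.0, "succ": 1.0, "co2": 1.0, "qh2": 1.0},
     0.0, 100.0, 0.0, "thr_g1"),
    ("SUCD", {"succ": -1.0, "q": -1.0, "fum": 1.0, "qh2": 1.0}, 0.0, 100.0, 0.0, "bot_g4"),
    ("FUM", {"fum": -1.0, "mal": 1.0}, -100.0, 100.0, 0.0, "bot_g5"),
    ("MDH", {"mal": -1.0, "q": -1.0, "oaa": 1.0, "qh2": 1.0}, 0.0, 100.0, 0.0, "bot_g6"),
    ("METB", {"akg": -1.0, "metx": 1.0}, 0.0, 100.0, 0.0, "thr_g2"),
    ("BIO", {"akg": -1.0, "bm": 1.0}, 0.0, 100.0, 1.0, ""),
    ("EX_bm", {"bm": -1.0}, 0.0, 100.0, 0.0, ""),
    ("EX_co2", {"co2": 1.0}, -100.0, 100.0, 0.0, ""),
    ("EX_q", {"q": 1.0}, 0.0, 100.0, 0.0, ""),
    ("EX_qh2", {"qh2": -1.0}, 0.0, 100.0, 0.0, ""),
    ("DM_metx", {"metx": -1.0}, 0.0, 100.0, 0.0, ""),
]


def _mini_core(spec: FixtureSpec):
    rxns = [
        Reaction(rid, dict(st), lb, ub, objective_coeff=obj, gpr=gpr)
        for rid, st, lb, ub, obj, gpr in _MINI_REACTIONS
    ]
    net = MetabolicNetwork(_mets(sorted(_MINI_FORMATION)), rxns)
    config = ThermoConfig()
    gt = GroundTruth(growth_reaction="BIO", growth_value=2.0)
    for r in rxns:
        if r.is_exchange or r.objective_coeff:
            continue
        drg0 = sum(c * _MINI_FORMATION[m] for m, c in r.stoichiometry.items())
        gt.expected_classes[r.id] = _expected_label(r.stoichiometry, drg0, config, set())
    return net, _table(dict(_MINI_FORMATION), spec.formation_se, []), gt


# ---------------------------------------------------------------------------
# randomised small fixtures (oracle sweeps)
# ---------------------------------------------------------------------------


def random_fixture(seed: int) -> tuple[MetabolicNetwork, ThermoTable, GroundTruth]:
    """A small random feasible network for enumeration-oracle sweeps.

    Topology drawn from the chain/branch/futile templates with randomised
    chain length, energies, uptake bound and one optional extra edge;
    at most ~8 constrained directions so exhaustive binary enumeration
    stays cheap.
    """
    rng = np.random.default_rng(seed)
    kind = ("linear_chain", "branched", "futile_cycle")[int(rng.integers(3))]
    sub_seed = int(rng.integers(2**31 - 1))
    spec = FixtureSpec(kind=kind, seed=sub_seed, n_reactions=int(rng.integers(5, 9)))
    net, table, gt = make_network_fixture(spec)
    if kind != "futile_cycle" and rng.random() < 0.5:
        # one extra internal edge between random distinct internal metabolites,
        # reversible half the time (adds a reverse direction binary)
        internal = [m.id for m in net.metabolites]
        i, j = rng.choice(len(internal), size=2, replace=False)
        lb = -float(rng.uniform(5.0, 50.0)) if rng.random() < 0.5 else 0.0
        extra = Reaction(
            "Rx", {internal[int(i)]: -1.0, internal[int(j)]: 1.0},
            lb, float(rng.uniform(5.0, 50.0)),
        )
        net = MetabolicNetwork(net.metabolites, net.reactions[:-1] + [extra, net.reactions[-1]])
    return net, table, gt


# ---------------------------------------------------------------------------
# expression fixtures
# ---------------------------------------------------------------------------


def make_expression_fixture(
    n_genes_per_class: int = 10,
    n_experiments: int = 10,
    dispersion_regulated: float = 3.0,
    dispersion_bottleneck: float = 1.0,
    cv_fail_frac: float = 0.2,
    seed: int = 0,
) -> tuple[ExpressionDataset, dict[str, str]]:
    """Expression matrix with planted wide (regulated) and narrow
    (bottleneck) genes; returns (dataset, gene -> class label).

    Fold changes are N(0, dispersion^2) on the log2 scale; each entry's
    CV is < 0.2 with probability 1 - cv_fail_frac and >= 0.2 otherwise.
    Equal dispersions are allowed (null-calibration runs).
    """
    if n_experiments < 2:
        raise ValueError("need at least 2 experiments for a range")
    if not (dispersion_regulated >= dispersion_bottleneck > 0):
        raise ValueError("need dispersion_regulated >= dispersion_bottleneck > 0")
    rng = np.random.default_rng(seed)
    experiments = [f"exp{k + 1}" for k in range(n_experiments)]
    fold_changes: dict[tuple[str, str], tuple[float, float]] = {}
    labels: dict[str, str] = {}
    for label, disp, prefix in (
        ("regulatory_candidate", dispersion_regulated, "reg"),
        ("bottleneck", dispersion_bottleneck, "bot"),
    ):
        for g in range(n_genes_per_class):
            gene = f"{prefix}_g{g + 1}"
            labels[gene] = label
            for exp in experiments:
                fc = float(rng.normal(0.0, disp))
                if rng.random() < cv_fail_frac:
                    cv = float(rng.uniform(0.2, 0.4))
                else:
                    cv = float(rng.uniform(0.0, 0.2))
                fold_changes[(gene, exp)] = (fc, cv)
    return ExpressionDataset(experiments=experiments, fold_changes=fold_changes), labels


def write_expression_fixture(dataset: ExpressionDataset, outdir) -> list:
    """One TSV per experiment, named after the experiment id."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for exp in dataset.experiments:
        p = outdir / f"{exp}.tsv"
        with open(p, "w") as fh:
            fh.write("gene\tfold_change\tcv\n")
            for (gene, e), (fc, cv) in sorted(dataset.fold_changes.items()):
                if e == exp:
                    fh.write(f"{gene}\t{fc!r}\t{cv!r}\n")
        paths.append(p)
    return paths
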