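"""Readers, writers and validation for metabolic networks, thermodynamic
tables, expression tables and gene-reaction (GPR) associations.

The native on-disk dialect is plain tab-separated text so fixtures stay
diffable:

``metabolites.tsv``
    columns ``id  name  compartment  is_water  is_proton``

``reactions.tsv``
    columns ``id  formula  lower_bound  upper_bound  objective_coeff  gpr``
    where ``formula`` is a signed coefficient list such as
    ``-1 ac_c + -1 oaa_c + 1 cit_c`` (negative = consumed).

``thermo.tsv``
    columns ``scope  id  dg  se`` with ``scope`` in {metabolite, reaction},
    ``dg`` a kcal/mol value or the literal ``UNKNOWN``.

``<experiment>.tsv`` (expression)
    columns ``gene  fold_change  cv`` (log2 fold change, coefficient of
    variation), one file per experiment.

SBML Level 3 core import is supported through COBRApy's reader.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger("thermoflux")


class ParseError(ValueError):
    """A file could not be parsed in the declared dialect."""


class ValidationError(ValueError):
    """A parsed object violates a structural invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    is_water: bool = False
    is_proton: bool = False


@dataclass
class Reaction:
    """One column of the stoichiometric matrix.

    ``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = substrate). Bounds are in mmol/gdw/hr.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: str = ""
    objective_coeff: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        nz = [c for c in self.stoichiometry.values() if c != 0.0]
        return len(nz) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0 and self.upper_bound > 0.0


@dataclass
class MetabolicNetwork:
    metabolites: list[Metabolite]
    reactions: list[Reaction]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.metabolites:
            if m.id in seen:
                raise ValidationError(f"duplicate metabolite id {m.id!r}")
            if not m.compartment:
                raise ValidationError(f"metabolite {m.id!r}: empty compartment")
            seen.add(m.id)
        rseen: set[str] = set()
        met_ids = seen
        for r in self.reactions:
            if r.id in rseen:
                raise ValidationError(f"duplicate reaction id {r.id!r}")
            rseen.add(r.id)
            missing = set(r.stoichiometry) - met_ids
            if missing:
                raise ValidationError(
                    f"reaction {r.id!r} references undeclared metabolites: "
                    f"{sorted(missing)}"
                )

    @property
    def m(self) -> int:
        return len(self.metabolites)

    @property
    def n(self) -> int:
        return len(self.reactions)

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def stoichiometric_matrix(self):
        """Dense S (m x n) as a numpy array, rows/cols in list order."""
        import numpy as np

        idx = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((self.m, self.n))
        for j, r in enumerate(self.reactions):
            for met, coef in r.stoichiometry.items():
                S[idx[met], j] = coef
        return S

    def is_transport(self, rxn_id: str) -> bool:
        """Heuristic: the reaction moves a species between compartments.

        A species stem (metabolite id with a trailing ``_<compartment>``
        suffix stripped) appearing on both sides in different compartments
        marks a transporter.
        """
        r = self.reaction(rxn_id)
        comp = {m.id: m.compartment for m in self.metabolites}
        stems: dict[str, set[str]] = {}
        for met, coef in r.stoichiometry.items():
            stem = re.sub(r"_[a-zA-Z0-9]+$", "", met)
            stems.setdefault(stem, set()).add(comp[met])
        return any(len(cs) > 1 for cs in stems.values())


UNKNOWN = object()  # sentinel: formation energy not estimable


@dataclass
class ThermoTable:
    """Standard transformed free energies (kcal/mol) with standard errors.

    ``formation_energies`` maps metabolite id to ``(value, se)`` or to the
    module-level ``UNKNOWN`` sentinel. ``reaction_energies``, when present,
    override reaction energies assembled from formation energies.
    """

    formation_energies: dict[str, object] = field(default_factory=dict)
    reaction_energies: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mid, entry in self.formation_energies.items():
            if entry is UNKNOWN:
                continue
            value, se = entry
            if not math.isfinite(value):
                raise ValidationError(f"{mid!r}: non-finite formation energy")
            if se < 0:
                raise ValidationError(f"{mid!r}: negative standard error")
        for rid, (value, se) in self.reaction_energies.items():
            if se < 0:
                raise ValidationError(f"{rid!r}: negative standard error")

    def is_unknown(self, met_id: str) -> bool:
        return self.formation_energies.get(met_id, UNKNOWN) is UNKNOWN


@dataclass
class ExpressionDataset:
    """Gene x experiment log2 fold changes with per-entry CV."""

    experiments: list[str]
    fold_changes: dict[tuple[str, str], tuple[float, float]]

    @property
    def genes(self) -> list[str]:
        return sorted({g for g, _ in self.fold_changes})

    def entries_for_gene(self, gene: str) -> list[tuple[str, float, float]]:
        out = []
        for exp in self.experiments:
            key = (gene, exp)
            if key in self.fold_changes:
                fc, cv = self.fold_changes[key]
                out.append((exp, fc, cv))
        return out


# ---------------------------------------------------------------------------
# formula strings
# ---------------------------------------------------------------------------


def parse_formula(formula: str, *, line: int | None = None) -> dict[str, float]:
    """Parse a signed coefficient list: ``-1 a + -2 b + 1.5 c``.

    An optional ``<compartment>:`` prefix is accepted and ignored
    (compartments are carried by the metabolite table).
    """
    where = f" (line {line})" if line is not None else ""
    body = formula.split(":", 1)[1] if ":" in formula else formula
    stoich: dict[str, float] = {}
    for term in body.split("+"):
        term = term.strip()
        if not term:
            raise ParseError(f"empty term in formula {formula!r}{where}")
        parts = term.split()
        if len(parts) != 2:
            raise ParseError(f"bad term {term!r} in formula{where}")
        try:
            coef = float(parts[0])
        except ValueError as exc:
            raise ParseError(f"bad coefficient {parts[0]!r}{where}") from exc
        met = parts[1]
        stoich[met] = stoich.get(met, 0.0) + coef
    return stoich


def format_formula(stoich: Mapping[str, float]) -> str:
    terms = []
    for met in stoich:
        coef = stoich[met]
        terms.append(f"{coef:g} {met}")
    return " + ".join(terms)


# ---------------------------------------------------------------------------
# network I/O
# ---------------------------------------------------------------------------

_BOOL = {"1": True, "true": True, "yes": True, "0": False, "false": False, "no": False, "": False}


def _read_tsv(path: Path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    rows = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        rows.append((i, line.split("\t")))
    return header, rows


def read_network(path: str | Path, format: str = "tsv") -> MetabolicNetwork:
    """Read a metabolic network.

    ``format='tsv'``: *path* is a directory holding ``metabolites.tsv`` and
    ``reactions.tsv`` in the dialect documented in the module docstring.
    ``format='sbml'``: *path* is an SBML Level 3 file (read via COBRApy).
    Reaction and metabolite order is file order.
    """
    path = Path(path)
    if format == "sbml":
        return _read_sbml(path)
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    if not path.is_dir():
        raise ParseError(f"{path}: expected a directory for the TSV dialect")

    mpath = path / "metabolites.tsv"
    header, rows = _read_tsv(mpath)
    col = {c: i for i, c in enumerate(header)}
    for required in ("id", "compartment"):
        if required not in col:
            raise ParseError(f"{mpath}: missing column {required!r}")
    mets = []
    for line_no, row in rows:
        try:
            mets.append(
                Metabolite(
                    id=row[col["id"]],
                    name=row[col["name"]] if "name" in col else "",
                    compartment=row[col["compartment"]],
                    is_water=_BOOL[row[col["is_water"]].lower()] if "is_water" in col else False,
                    is_proton=_BOOL[row[col["is_proton"]].lower()] if "is_proton" in col else False,
                )
            )
        except (IndexError, KeyError) as exc:
            raise ParseError(f"{mpath}: malformed row at line {line_no}") from exc

    rpath = path / "reactions.tsv"
    header, rows = _read_tsv(rpath)
    col = {c: i for i, c in enumerate(header)}
    for required in ("id", "formula", "lower_bound", "upper_bound"):
        if required not in col:
            raise ParseError(f"{rpath}: missing column {required!r}")
    rxns = []
    for line_no, row in rows:
        try:
            rxns.append(
                Reaction(
                    id=row[col["id"]],
                    stoichiometry=parse_formula(row[col["formula"]], line=line_no),
                    lower_bound=float(row[col["lower_bound"]]),
                    upper_bound=float(row[col["upper_bound"]]),
                    objective_coeff=float(row[col["objective_coeff"]])
                    if "objective_coeff" in col and row[col["objective_coeff"]]
                    else 0.0,
                    gpr=row[col["gpr"]] if "gpr" in col and len(row) > col["gpr"] else "",
                    name=row[col["name"]] if "name" in col else "",
                )
            )
        except (IndexError, ValueError) as exc:
            if isinstance(exc, (ParseError, ValidationError)):
                raise
            raise ParseError(f"{rpath}: malformed row at line {line_no}: {exc}") from exc
    return MetabolicNetwork(metabolites=mets, reactions=rxns)


def _read_sbml(path: Path) -> MetabolicNetwork:
    from cobra.io import read_sbml_model

    model = read_sbml_model(str(path))
    mets = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            compartment=m.compartment or "c",
            is_water=m.id.lower().startswith(("h2o", "water")),
            is_proton=m.id.lower().split("_")[0] in {"h", "h+"},
        )
        for m in model.metabolites
    ]
    rxns = [
        Reaction(
            id=r.id,
            stoichiometry={m.id: coef for m, coef in r.metabolites.items()},
            lower_bound=r.lower_bound,
            upper_bound=r.upper_bound,
            objective_coeff=r.objective_coefficient,
            gpr=str(r.gpr) if r.gpr else "",
            name=r.name or "",
        )
        for r in model.reactions
    ]
    return MetabolicNetwork(metabolites=mets, reactions=rxns)


def write_network(network: MetabolicNetwork, path: str | Path) -> None:
    """Write ``metabolites.tsv`` and ``reactions.tsv`` under *path*."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "metabolites.tsv", "w") as fh:
        fh.write("id\tname\tcompartment\tis_water\tis_proton\n")
        for m in network.metabolites:
            fh.write(
                f"{m.id}\t{m.name}\t{m.compartment}\t{int(m.is_water)}\t{int(m.is_proton)}\n"
            )
    with open(path / "reactions.tsv", "w") as fh:
        fh.write("id\tname\tformula\tlower_bound\tupper_bound\tobjective_coeff\tgpr\n")
        for r in network.reactions:
            fh.write(
                f"{r.id}\t{r.name}\t{format_formula(r.stoichiometry)}\t"
                f"{r.lower_bound:g}\t{r.upper_bound:g}\t{r.objective_coeff:g}\t{r.gpr}\n"
            )


# ---------------------------------------------------------------------------
# thermodynamic table I/O
# ---------------------------------------------------------------------------


def read_thermo_table(
    path: str | Path, network: MetabolicNetwork | None = None
) -> tuple[ThermoTable, list[str]]:
    """Read ``thermo.tsv``; returns the table plus a warning list.

    Rows whose ``dg`` field is the literal ``UNKNOWN`` are preserved as
    unknown (never coerced to zero). If the ``se`` column is absent every
    standard error defaults to 0 and a warning is recorded. If *network*
    is given, ids absent from it are reported as warnings.
    """
    path = Path(path)
    header, rows = _read_tsv(path)
    col = {c: i for i, c in enumerate(header)}
    for required in ("scope", "id", "dg"):
        if required not in col:
            raise ParseError(f"{path}: missing column {required!r}")
    warnings: list[str] = []
    if "se" not in col:
        warnings.append("se column absent; all standard errors default to 0")
        logger.warning("%s: %s", path, warnings[-1])

    formation: dict[str, object] = {}
    reaction: dict[str, tuple[float, float]] = {}
    for line_no, row in rows:
        scope = row[col["scope"]]
        ident = row[col["id"]]
        raw = row[col["dg"]]
        if raw.upper() == "UNKNOWN":
            if scope != "metabolite":
                raise ParseError(f"{path} line {line_no}: UNKNOWN only valid for metabolites")
            formation[ident] = UNKNOWN
            continue
        try:
            value = float(raw)
        except ValueError as exc:
            raise ParseError(f"{path} line {line_no}: bad dg value {raw!r}") from exc
        se = 0.0
        if "se" in col and len(row) > col["se"] and row[col["se"]]:
            se = float(row[col["se"]])
        if se < 0:
            raise ValidationError(f"{path} line {line_no}: negative se {se}")
        if scope == "metabolite":
            formation[ident] = (value, se)
        elif scope == "reaction":
            reaction[ident] = (value, se)
        else:
            raise ParseError(f"{path} line {line_no}: unknown scope {scope!r}")

    table = ThermoTable(formation_energies=formation, reaction_energies=reaction)
    if network is not None:
        met_ids = {m.id for m in network.metabolites}
        rxn_ids = {r.id for r in network.reactions}
        for mid in formation:
            if mid not in met_ids:
                warnings.append(f"metabolite {mid!r} not in network")
        for rid in reaction:
            if rid not in rxn_ids:
                warnings.append(f"reaction {rid!r} not in network")
    return table, warnings


def write_thermo_table(table: ThermoTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("scope\tid\tdg\tse\n")
        for mid, entry in table.formation_energies.items():
            if entry is UNKNOWN:
                fh.write(f"metabolite\t{mid}\tUNKNOWN\t\n")
            else:
                value, se = entry
                fh.write(f"metabolite\t{mid}\t{value!r}\t{se!r}\n")
        for rid, (value, se) in table.reaction_energies.items():
            fh.write(f"reaction\t{rid}\t{value!r}\t{se!r}\n")


# ---------------------------------------------------------------------------
# expression I/O
# ---------------------------------------------------------------------------


def read_expression(paths: Sequence[str | Path]) -> ExpressionDataset:
    """Read one TSV per experiment (columns gene, fold_change, cv).

    Experiments are keyed by filename stem; a gene may be present in any
    subset of experiments. An empty path list yields an empty dataset.
    """
    experiments: list[str] = []
    fold_changes: dict[tuple[str, str], tuple[float, float]] = {}
    for p in paths:
        p = Path(p)
        exp = p.stem
        experiments.append(exp)
        header, rows = _read_tsv(p)
        col = {c: i for i, c in enumerate(header)}
        for required in ("gene", "fold_change", "cv"):
            if required not in col:
                raise ParseError(f"{p}: missing column {required!r}")
        for line_no, row in rows:
            gene = row[col["gene"]]
            try:
                fc = float(row[col["fold_change"]])
                cv = float(row[col["cv"]])
            except ValueError as exc:
                raise ParseError(f"{p} line {line_no}: non-numeric value") from exc
            if cv < 0:
                raise ValidationError(f"{p} line {line_no}: negative cv")
            fold_changes[(gene, exp)] = (fc, cv)
    return ExpressionDataset(experiments=experiments, fold_changes=fold_changes)


# ---------------------------------------------------------------------------
# GPR flattening
# ---------------------------------------------------------------------------

_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def genes_for_reaction(network: MetabolicNetwork, reaction_id: str) -> set[str]:
    """Flatten a reaction's boolean GPR rule to its gene set.

    The boolean structure (and/or nesting) is discarded: every gene that
    appears anywhere in the rule is returned, which is what per-gene
    expression joins need. Unbalanced parentheses raise :class:`ParseError`.
    """
    gpr = network.reaction(reaction_id).gpr
    return flatten_gpr(gpr)


def flatten_gpr(gpr: str) -> set[str]:
    if not gpr.strip():
        return set()
    depth = 0
    genes: set[str] = set()
    for tok in _GPR_TOKEN.findall(gpr):
        if tok == "(":
            depth += 1
        elif tok == ")":
            depth -= 1
            if depth < 0:
                raise ParseError(f"unbalanced parentheses in GPR {gpr!r}")
        elif tok.lower() in ("and", "or"):
            continue
        else:
            genes.add(tok)
    if depth != 0:
        raise ParseError(f"unbalanced parentheses in GPR {gpr!r}")
    return genes
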