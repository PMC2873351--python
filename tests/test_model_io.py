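"""Network / thermo / expression readers and GPR flattening."""

import pytest

from thermoflux import model_io as io
from thermoflux.model_io import (
    Metabolite,
    MetabolicNetwork,
    ParseError,
    Reaction,
    UNKNOWN,
    ValidationError,
    flatten_gpr,
    read_expression,
    read_network,
    read_thermo_table,
    write_network,
)


def small_network():
    mets = [Metabolite("A"), Metabolite("B"), Metabolite("C")]
    rxns = [
        Reaction("EX_A", {"A": 1.0}, 0.0, 5.0),
        Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, 100.0, gpr="(g1 and g2) or g3"),
        Reaction("R2", {"B": -1.0, "C": 1.0}, -10.0, 100.0),
        Reaction("EX_C", {"C": -1.0}, 0.0, 100.0, objective_coeff=1.0),
    ]
    return MetabolicNetwork(mets, rxns)


class TestNetworkIO:
    def test_roundtrip_preserves_every_field(self, tmp_path):
        net = small_network()
        write_network(net, tmp_path)
        back = read_network(tmp_path)
        assert (back.m, back.n) == (3, 4)
        for orig, got in zip(net.reactions, back.reactions):
            assert got.id == orig.id
            assert got.stoichiometry == orig.stoichiometry
            assert (got.lower_bound, got.upper_bound) == (orig.lower_bound, orig.upper_bound)
            assert got.gpr == orig.gpr
            assert got.objective_coeff == orig.objective_coeff
        for orig, got in zip(net.metabolites, back.metabolites):
            assert got == orig

    def test_reading_is_deterministic(self, tmp_path):
        write_network(small_network(), tmp_path)
        a, b = read_network(tmp_path), read_network(tmp_path)
        assert [r.id for r in a.reactions] == [r.id for r in b.reactions]
        assert a.stoichiometric_matrix().tolist() == b.stoichiometric_matrix().tolist()

    def test_undeclared_metabolite_rejected(self):
        with pytest.raises(ValidationError, match="undeclared"):
            MetabolicNetwork([Metabolite("A")], [Reaction("R", {"A": -1, "Z": 1}, 0, 1)])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            MetabolicNetwork([Metabolite("A"), Metabolite("A")], [])

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValidationError, match="lower_bound"):
            Reaction("R", {"A": -1.0}, 5.0, 1.0)

    def test_malformed_row_names_line(self, tmp_path):
        write_network(small_network(), tmp_path)
        p = tmp_path / "reactions.tsv"
        p.write_text(p.read_text() + "BAD\tname\tnot a formula\tx\ty\t\t\n")
        with pytest.raises(ParseError, match="line 6"):
            read_network(tmp_path)

    def test_sbml_import(self, tmp_path):
        cobra = pytest.importorskip("cobra")
        from cobra.io import write_sbml_model

        model = cobra.Model("toy")
        a = cobra.Metabolite("A_c", compartment="c")
        b = cobra.Metabolite("B_c", compartment="c")
        r = cobra.Reaction("R1")
        model.add_reactions([r])
        r.add_metabolites({a: -1.0, b: 1.0})
        r.bounds = (0.0, 10.0)
        r.gene_reaction_rule = "g1 or g2"
        path = tmp_path / "toy.xml"
        write_sbml_model(model, str(path))
        net = read_network(path, format="sbml")
        assert [m.id for m in net.metabolites] == ["A_c", "B_c"]
        rxn = net.reaction("R1")
        assert rxn.stoichiometry == {"A_c": -1.0, "B_c": 1.0}
        assert io.flatten_gpr(rxn.gpr) == {"g1", "g2"}

    def test_exchange_detection(self):
        net = small_network()
        assert net.reaction("EX_A").is_exchange
        assert not net.reaction("R1").is_exchange

    def test_transport_heuristic(self):
        net = MetabolicNetwork(
            [Metabolite("ac_e", compartment="e"), Metabolite("ac_c", compartment="c")],
            [Reaction("ACt", {"ac_e": -1.0, "ac_c": 1.0}, 0, 10)],
        )
        assert net.is_transport("ACt")


class TestFormula:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("-1 a + 1 b", {"a": -1.0, "b": 1.0}),
            ("cytosol: -1 ac + 1 actp", {"ac": -1.0, "actp": 1.0}),
            ("-2 a + 1.5 b + -1 c", {"a": -2.0, "b": 1.5, "c": -1.0}),
        ],
    )
    def test_parse(self, text, expected):
        assert io.parse_formula(text) == expected

    def test_format_parse_roundtrip(self):
        stoich = {"a": -2.0, "b": 1.5}
        assert io.parse_formula(io.format_formula(stoich)) == stoich

    def test_bad_term_raises(self):
        with pytest.raises(ParseError):
            io.parse_formula("a + b")


class TestThermoTable:
    def _write(self, tmp_path, body, header="scope\tid\tdg\tse"):
        p = tmp_path / "thermo.tsv"
        p.write_text(header + "\n" + body)
        return p

    def test_formation_row(self, tmp_path):
        p = self._write(tmp_path, "metabolite\tatp_c\t-673.85\t1.2\n")
        table, warnings = read_thermo_table(p)
        assert table.formation_energies["atp_c"] == (-673.85, 1.2)
        assert warnings == []

    def test_unknown_preserved_not_zero(self, tmp_path):
        p = self._write(tmp_path, "metabolite\twildmet_c\tUNKNOWN\t\n")
        table, _ = read_thermo_table(p)
        assert table.formation_energies["wildmet_c"] is UNKNOWN
        assert table.is_unknown("wildmet_c")

    def test_missing_se_column_defaults_zero_with_warning(self, tmp_path):
        p = self._write(tmp_path, "metabolite\ta\t-1.0\n", header="scope\tid\tdg")
        table, warnings = read_thermo_table(p)
        assert table.formation_energies["a"] == (-1.0, 0.0)
        assert any("se" in w for w in warnings)

    def test_negative_se_rejected(self, tmp_path):
        p = self._write(tmp_path, "metabolite\ta\t-1.0\t-0.5\n")
        with pytest.raises(ValidationError, match="negative se"):
            read_thermo_table(p)

    def test_ids_absent_from_network_warned(self, tmp_path):
        p = self._write(tmp_path, "metabolite\tnot_there\t-1.0\t0\n")
        _, warnings = read_thermo_table(p, small_network())
        assert any("not_there" in w for w in warnings)

    def test_reaction_rows_become_overrides(self, tmp_path):
        p = self._write(tmp_path, "reaction\tR1\t-3.5\t0.2\n")
        table, _ = read_thermo_table(p)
        assert table.reaction_energies["R1"] == (-3.5, 0.2)


class TestExpressionIO:
    def _write(self, path, genes):
        with open(path, "w") as fh:
            fh.write("gene\tfold_change\tcv\n")
            for g, fc, cv in genes:
                fh.write(f"{g}\t{fc}\t{cv}\n")

    def test_two_files_five_genes(self, tmp_path):
        g = [(f"g{i}", 0.5 * i, 0.1) for i in range(5)]
        self._write(tmp_path / "expA.tsv", g)
        self._write(tmp_path / "expB.tsv", g[:3])
        ds = read_expression([tmp_path / "expA.tsv", tmp_path / "expB.tsv"])
        assert ds.experiments == ["expA", "expB"]
        assert len(ds.fold_changes) == 8

    def test_gene_in_one_file_only(self, tmp_path):
        self._write(tmp_path / "e1.tsv", [("solo", 1.0, 0.1)])
        self._write(tmp_path / "e2.tsv", [("other", 2.0, 0.1)])
        ds = read_expression([tmp_path / "e1.tsv", tmp_path / "e2.tsv"])
        assert ("solo", "e1") in ds.fold_changes
        assert ("solo", "e2") not in ds.fold_changes

    def test_empty_path_list_is_empty_dataset(self):
        ds = read_expression([])
        assert ds.experiments == [] and ds.fold_changes == {}

    def test_non_numeric_fold_change_raises(self, tmp_path):
        self._write(tmp_path / "e.tsv", [("g", "NaNope", 0.1)])
        with pytest.raises(ParseError, match="non-numeric"):
            read_expression([tmp_path / "e.tsv"])


class TestGpr:
    @pytest.mark.parametrize(
        "gpr,expected",
        [
            ("(g1 and g2) or g3", {"g1", "g2", "g3"}),
            ("", set()),
            ("g1", {"g1"}),
            ("g1 AND (g2 OR g3) AND g1", {"g1", "g2", "g3"}),
        ],
    )
    def test_flatten(self, gpr, expected):
        assert flatten_gpr(gpr) == expected

    def test_unbalanced_parens_raise(self):
        with pytest.raises(ParseError, match="parenthes"):
            flatten_gpr("g1 and (g2 or")

    def test_lookup_by_reaction(self):
        net = small_network()
        from thermoflux.model_io import genes_for_reaction

        assert genes_for_reaction(net, "R1") == {"g1", "g2", "g3"}
        assert genes_for_reaction(net, "R2") == set()
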