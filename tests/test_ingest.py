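"""Expression-table parsing, symbol canonicalization, ortholog mapping and
common-universe construction."""

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from regensig import (
    AliasTable,
    ExpressionExperiment,
    InputError,
    OrthologMap,
    ParseError,
    build_common_universe,
    canonicalize_symbols,
    map_to_human,
    read_expression_table,
)
from regensig.ranking import fold_change_table


def write_expr(tmp_path, rows, samples=("s1", "s2", "s3", "s4"), name="expr.tsv"):
    header = "probe_id\tgene_symbol\t" + "\t".join(samples)
    path = tmp_path / name
    path.write_text("\n".join([header] + rows) + "\n")
    design = tmp_path / "design.tsv"
    groups = ["high_regeneration", "high_regeneration", "low_regeneration", "low_regeneration"]
    design.write_text(
        "sample\tgroup\n" + "\n".join(f"{s}\t{g}" for s, g in zip(samples, groups)) + "\n"
    )
    return path, design


class TestReadExpressionTable:
    def test_parses_probes_and_both_groups(self, tmp_path):
        path, design = write_expr(
            tmp_path,
            ["p1\tOAS1\t8\t6\t2\t1", "p2\tOAS2\t4\t4\t4\t4", "p3\tMX1\t1\t1\t2\t2"],
        )
        exp = read_expression_table(path, design, species="human", platform="array")
        assert len(exp.table) == 3
        assert len(exp.samples_in_group("high_regeneration")) == 2
        assert len(exp.samples_in_group("low_regeneration")) == 2

    def test_design_sample_missing_from_header_names_it(self, tmp_path):
        path, design = write_expr(tmp_path, ["p1\tOAS1\t8\t6\t2\t1"])
        design.write_text("sample\tgroup\nGHOST\thigh_regeneration\ns3\tlow_regeneration\n")
        with pytest.raises(ParseError, match="GHOST"):
            read_expression_table(path, design, species="human", platform="array")

    def test_empty_gene_symbol_rows_dropped_and_counted(self, tmp_path):
        path, design = write_expr(
            tmp_path, ["p1\tOAS1\t8\t6\t2\t1", "p2\t\t4\t4\t4\t4", "p3\tMX1\t1\t1\t2\t2"]
        )
        exp = read_expression_table(path, design, species="human", platform="array")
        assert len(exp.table) == 2
        assert exp.meta["n_dropped_empty_symbol"] == 1

    def test_non_numeric_intensity_rejected(self, tmp_path):
        path, design = write_expr(tmp_path, ["p1\tOAS1\t8\tNOPE\t2\t1"])
        with pytest.raises(ParseError, match="s2"):
            read_expression_table(path, design, species="human", platform="array")

    def test_precomputed_fc_column(self, tmp_path):
        path = tmp_path / "fc.tsv"
        path.write_text("probe_id\tgene_symbol\tlogratio\np1\tOAS1\t2.5\np2\tMX1\t-1.0\n")
        exp = read_expression_table(
            path, None, species="human", platform="rnaseq", fc_column="logratio"
        )
        assert not exp.has_matrix
        assert exp.table["log2fc"].tolist() == [2.5, -1.0]

    def test_duplicate_probe_ids_rejected(self, tmp_path):
        path, design = write_expr(tmp_path, ["p1\tOAS1\t1\t1\t1\t1", "p1\tMX1\t2\t2\t2\t2"])
        with pytest.raises(InputError, match="p1"):
            read_expression_table(path, design, species="human", platform="array")


def make_experiment(probe_symbol_fc, species="mouse"):
    """Precomputed-fc experiment from [(probe, symbol, fc)] triples."""
    table = pd.DataFrame(probe_symbol_fc, columns=["probe_id", "gene_symbol", "log2fc"])
    return ExpressionExperiment(
        experiment_id="e1", species=species, platform="test", table=table, design=None
    )


class TestCanonicalizeSymbols:
    aliases = AliasTable(
        pd.DataFrame(
            [
                ("Il1f6", "Il36a", "mouse"),
                ("Oasl2", "Oasl2", "mouse"),  # canonical fixed point
                ("OASL1", "OASL", "human"),
            ],
            columns=["alias", "canonical", "species"],
        )
    )

    def test_alias_updated_to_current_nomenclature(self):
        exp = make_experiment([("p1", "Il1f6", 1.0)])
        out = canonicalize_symbols(exp, self.aliases)
        assert out.table["gene_symbol"].tolist() == ["Il36a"]
        assert out.meta["n_alias_mapped"] == 1

    def test_unknown_and_canonical_symbols_pass_through(self):
        exp = make_experiment([("p1", "Oas1a", 1.0), ("p2", "Oasl2", 2.0)])
        out = canonicalize_symbols(exp, self.aliases)
        assert out.table["gene_symbol"].tolist() == ["Oas1a", "Oasl2"]
        assert out.meta["n_alias_unmapped"] == 1

    def test_species_scoped_and_idempotent(self):
        exp = make_experiment([("p1", "Il1f6", 1.0), ("p2", "OASL1", 2.0)])
        once = canonicalize_symbols(exp, self.aliases)
        twice = canonicalize_symbols(once, self.aliases)
        # the human alias must not fire on a mouse experiment
        assert once.table["gene_symbol"].tolist() == ["Il36a", "OASL1"]
        assert twice.table["gene_symbol"].tolist() == once.table["gene_symbol"].tolist()


class TestMapToHuman:
    orthologs = OrthologMap(
        pd.DataFrame(
            [
                ("Oas1a", "OAS1", "HomoloGene"),
                ("Oas1g", "OAS1", "HCOP"),
                ("Mx1", "MX1", "HomoloGene"),
                ("Oas1a", "OAS1", "HCOP"),  # duplicate pair: collapsed on load
            ],
            columns=["mouse_symbol", "human_symbol", "source_db"],
        )
    )

    def test_duplicate_pairs_collapsed_on_load(self):
        assert len(self.orthologs.frame) == 3

    def test_direct_relabel(self):
        exp = make_experiment([("p1", "Oas1a", 1.0)])
        out, dropped = map_to_human(exp, self.orthologs)
        assert out.table["gene_symbol"].tolist() == ["OAS1"]
        assert dropped == []

    def test_two_mouse_genes_collapse_to_one_human_fold_change(self):
        """Expand-then-collapse: Oas1a and Oas1g probes both land under OAS1
        and the gene-level collapse yields a single value (their median)."""
        exp = make_experiment(
            [("p1", "Oas1a", 1.0), ("p2", "Oas1g", 3.0), ("p3", "Mx1", 2.0)]
        )
        out, _ = map_to_human(exp, self.orthologs)
        assert sorted(out.table["gene_symbol"]) == ["MX1", "OAS1", "OAS1"]
        fc = fold_change_table(out)
        assert fc.log2fc["OAS1"] == 2.0  # median of 1.0 and 3.0
        assert fc.n_probes["OAS1"] == 2

    def test_unmapped_gene_dropped_and_reported(self):
        exp = make_experiment([("p1", "Oas1a", 1.0), ("p2", "Gm1234", 5.0)])
        out, dropped = map_to_human(exp, self.orthologs)
        assert dropped == ["Gm1234"]
        assert "Gm1234" not in set(out.table["gene_symbol"])

    def test_human_experiment_passes_through(self):
        exp = make_experiment([("p1", "OAS1", 1.0)], species="human")
        out, dropped = map_to_human(exp, self.orthologs)
        assert out is exp and dropped == []

    def test_nothing_mappable_is_an_error(self):
        exp = make_experiment([("p1", "Gm0001", 1.0)])
        with pytest.raises(InputError):
            map_to_human(exp, self.orthologs)


class TestBuildCommonUniverse:
    @pytest.mark.parametrize(
        "sets, expected",
        [
            ({"e1": {"A", "B", "C"}, "e2": {"B", "C", "D"}}, ("B", "C")),
            ({"e1": {"A", "B"}, "e2": {"A", "B"}}, ("A", "B")),
            (
                {"e1": {"A", "B", "C"}, "e2": {"B", "C", "D"}, "e3": {"C", "D", "E"}},
                ("C",),
            ),
        ],
    )
    def test_intersection(self, sets, expected):
        assert build_common_universe(sets).genes == expected

    def test_dropped_genes_logged_per_experiment(self):
        uni = build_common_universe({"e1": {"A", "B"}, "e2": {"B", "C"}})
        assert uni.dropped == {"e1": ("A",), "e2": ("C",)}

    def test_empty_intersection_is_an_error(self):
        with pytest.raises(InputError):
            build_common_universe({"e1": {"A"}, "e2": {"B"}})

    @given(
        st.lists(
            st.sets(st.sampled_from("ABCDEFGH"), min_size=1, max_size=8),
            min_size=1,
            max_size=5,
        )
    )
    def test_order_invariant_and_never_invents_symbols(self, gene_sets):
        union = set().union(*gene_sets)
        forward = {f"e{i}": s for i, s in enumerate(gene_sets)}
        backward = {f"e{i}": s for i, s in enumerate(reversed(gene_sets))}
        try:
            u1 = build_common_universe(forward)
        except InputError:
            with pytest.raises(InputError):
                build_common_universe(backward)
            return
        u2 = build_common_universe(backward)
        assert u1.genes == u2.genes
        assert set(u1.genes) <= union
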