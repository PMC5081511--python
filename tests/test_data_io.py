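import networkx as nx
import numpy as np
import pandas as pd
import pytest

from lncmod.data_io import (
    FormatError,
    read_expression,
    read_go,
    read_ppi,
    write_expression,
    write_network,
)
from lncmod.simulate import generate_dataset

from conftest import make_go


def write_tsv(path, text):
    path.write_text(text)
    return str(path)


class TestReadExpression:
    def test_parses_genes_and_classes(self, tmp_path):
        m = write_tsv(tmp_path / "m.tsv",
                      "gene\tS1\tS2\tS3\tS4\nL1\t1\t2\t3\t4\nM1\t4\t3\t2\t1\nM2\t1\t1\t2\t2\n")
        c = write_tsv(tmp_path / "c.tsv", "L1\tlncRNA\nM1\tmRNA\nM2\tmRNA\n")
        expr = read_expression(m, c)
        assert expr.lnc_ids == ["L1"]
        assert expr.mrna_ids == ["M1", "M2"]
        assert expr.sample_ids == ["S1", "S2", "S3", "S4"]

    def test_duplicate_gene_id_rejected(self, tmp_path):
        m = write_tsv(tmp_path / "m.tsv",
                      "gene\tS1\tS2\tS3\nL1\t1\t2\t3\nL1\t1\t2\t3\n")
        c = write_tsv(tmp_path / "c.tsv", "L1\tlncRNA\n")
        with pytest.raises(FormatError, match="duplicate gene"):
            read_expression(m, c)

    def test_missing_class_rejected(self, tmp_path):
        m = write_tsv(tmp_path / "m.tsv", "gene\tS1\tS2\nL1\t1\t2\nM1\t2\t1\n")
        c = write_tsv(tmp_path / "c.tsv", "L1\tlncRNA\n")
        with pytest.raises(FormatError, match="without a class"):
            read_expression(m, c)

    def test_unknown_class_label_rejected(self, tmp_path):
        m = write_tsv(tmp_path / "m.tsv", "gene\tS1\tS2\nL1\t1\t2\n")
        c = write_tsv(tmp_path / "c.tsv", "L1\tpseudogene\n")
        with pytest.raises(FormatError, match="class labels"):
            read_expression(m, c)

    def test_non_numeric_cell_rejected(self, tmp_path):
        m = write_tsv(tmp_path / "m.tsv", "gene\tS1\tS2\nL1\t1\tlow\n")
        c = write_tsv(tmp_path / "c.tsv", "L1\tlncRNA\n")
        with pytest.raises(FormatError, match="non-numeric"):
            read_expression(m, c)

    def test_roundtrip_bit_identical(self, tmp_path):
        ds = generate_dataset(n_lnc=5, n_mrna=10, n_samples=6, n_planted=2,
                              partners_per_module=3, seed=4)
        write_expression(ds.expr, tmp_path / "m.tsv", tmp_path / "c.tsv")
        back = read_expression(tmp_path / "m.tsv", tmp_path / "c.tsv")
        # TSV text is the canonical interchange form: a second write of the
        # re-read matrix must reproduce the file byte for byte
        write_expression(back, tmp_path / "m2.tsv", tmp_path / "c2.tsv")
        assert (tmp_path / "m.tsv").read_bytes() == (tmp_path / "m2.tsv").read_bytes()
        assert back.gene_class == ds.expr.gene_class


class TestReadPpi:
    def test_self_and_duplicate_interactions_dropped(self, tmp_path):
        p = write_tsv(tmp_path / "ppi.tsv", "A\tB\nB\tA\nA\tA\nB\tC\n")
        g = read_ppi(p)
        assert {tuple(sorted(e)) for e in g.edges} == {("A", "B"), ("B", "C")}

    def test_cross_file_duplicates_collapse(self, tmp_path):
        p1 = write_tsv(tmp_path / "a.tsv", "A\tB\n")
        p2 = write_tsv(tmp_path / "b.tsv", "A\tB\n")
        g = read_ppi([p1, p2])
        assert g.number_of_edges() == 1

    def test_sif_layout(self, tmp_path):
        p = write_tsv(tmp_path / "net.sif", "A\tpp\tB\tC\nD\n")
        g = read_ppi(p)
        assert {tuple(sorted(e)) for e in g.edges} == {("A", "B"), ("A", "C")}
        assert "D" in g.nodes

    def test_empty_union_is_an_error(self, tmp_path):
        p = write_tsv(tmp_path / "ppi.tsv", "A\tA\n")
        with pytest.raises(FormatError, match="no interactions"):
            read_ppi(p)

    def test_dedup_idempotent_on_own_output(self, tmp_path):
        ds = generate_dataset(n_lnc=4, n_mrna=30, n_samples=5, n_planted=2,
                              partners_per_module=5, seed=9)
        paths = ds.write(tmp_path)
        g1 = read_ppi(paths["ppi"])
        write_network(g1, tmp_path / "again.tsv", "tsv")
        # re-read of the written edge list: strip the header line
        text = (tmp_path / "again.tsv").read_text().splitlines()[1:]
        (tmp_path / "again2.tsv").write_text(
            "\n".join("\t".join(l.split("\t")[:2]) for l in text) + "\n")
        g2 = read_ppi(tmp_path / "again2.tsv")
        assert {tuple(sorted(e)) for e in g1.edges} == {tuple(sorted(e)) for e in g2.edges}


class TestGoResource:
    def test_propagation_transitive_closure(self, chain_go):
        assert chain_go.propagated_annotations["g1"] == {"B", "A", "root"}

    def test_root_only_annotation(self, chain_go):
        assert chain_go.propagated_annotations["g2"] == {"root"}

    def test_term_genes_inverse_of_propagation(self, sibling_go):
        for gene, terms in sibling_go.propagated_annotations.items():
            for t in terms:
                assert gene in sibling_go.term_genes[t]
        for t, genes in sibling_go.term_genes.items():
            for g in genes:
                assert t in sibling_go.propagated_annotations[g]

    def test_propagated_superset_of_direct(self, sibling_go):
        for g, terms in sibling_go.direct_annotations.items():
            assert sibling_go.propagated_annotations[g] >= terms

    def test_cyclic_ontology_rejected(self):
        with pytest.raises(FormatError, match="cycle"):
            make_go(edges=[("A", "B"), ("B", "A")], direct={"g": {"A"}})

    def test_term_genes_match_bruteforce_ancestor_walk(self):
        rng = np.random.default_rng(5)
        terms = [f"T{i}" for i in range(15)]
        edges = [(terms[i], terms[int(rng.integers(0, i))]) for i in range(1, 15)]
        direct = {f"g{j}": {terms[int(rng.integers(0, 15))]} for j in range(30)}
        go = make_go(edges=edges, direct=direct)
        parent = {c: p for c, p in edges}
        for g, (t,) in ((g, tuple(ts)) for g, ts in direct.items()):
            walk = {t}
            while t in parent:
                t = parent[t]
                walk.add(t)
            assert go.propagated_annotations[g] == walk

    def test_obo_gaf_reader(self, tmp_path):
        (tmp_path / "go.obo").write_text(
            "format-version: 1.2\n\n[Term]\nid: GO:0000001\nname: root\n"
            "namespace: biological_process\n\n[Term]\nid: GO:0000002\nname: child\n"
            "namespace: biological_process\nis_a: GO:0000001 ! root\n"
        )
        (tmp_path / "ann.gaf").write_text(
            "!gaf-version: 2.1\n"
            "DB\tGENE1\tGENE1\t\tGO:0000002\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t\t\n"
            "DB\tGENE2\tGENE2\tNOT\tGO:0000002\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t\t\n"
            "DB\tGENE3\tGENE3\t\tGO:9999999\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t\t\n"
        )
        with pytest.warns(UserWarning, match="unknown"):
            go = read_go(tmp_path / "go.obo", tmp_path / "ann.gaf")
        assert go.propagated_annotations["GENE1"] == {"GO:0000002", "GO:0000001"}
        assert "GENE2" not in go.propagated_annotations  # NOT-qualified
        assert "GENE3" not in go.propagated_annotations  # unknown term skipped


class TestWriteNetwork:
    def test_sif_single_edge(self, tmp_path):
        g = nx.Graph([("A", "B")])
        write_network(g, tmp_path / "n.sif", "sif")
        assert (tmp_path / "n.sif").read_text() == "A\tpp\tB\n"

    def test_graphml_roundtrip_preserves_attributes(self, tmp_path):
        g = nx.Graph()
        g.add_edge("A", "B", score=0.5, jc=0.25)
        write_network(g, tmp_path / "n.graphml", "graphml")
        back = nx.read_graphml(tmp_path / "n.graphml")
        assert back.edges["A", "B"]["score"] == 0.5
        assert back.edges["A", "B"]["jc"] == 0.25

    def test_empty_network_writes_valid_document(self, tmp_path):
        write_network(nx.Graph(), tmp_path / "e.graphml", "graphml")
        assert nx.read_graphml(tmp_path / "e.graphml").number_of_nodes() == 0
        write_network(nx.Graph(), tmp_path / "e.sif", "sif")
        assert (tmp_path / "e.sif").read_text() == ""

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown network format"):
            write_network(nx.Graph([("A", "B")]), tmp_path / "x.bin", "xgmml")
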