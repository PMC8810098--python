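"""Cis windows, TF associations and tri-network assembly/export."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lncnet.config import AnalysisConfig
from lncnet.data_model import GeneSetCollection
from lncnet.enrichment import enrich_set
from lncnet.regulation import (OVERLAP, TriNetwork, build_tri_network,
                               call_cis_pairs, cis_candidates, export_network,
                               interval_gap, load_network, tf_associations)


def _annot_row(chrom, start, end):
    return pd.Series({"gene_symbol": "g", "biotype": "lncRNA",
                      "chrom": chrom, "start": start, "end": end,
                      "strand": "+"})


def _mrna_table(entries):
    return pd.DataFrame(
        {"gene_symbol": [f"g{i}" for i in range(len(entries))],
         "biotype": ["mRNA"] * len(entries),
         "chrom": [c for c, _, _ in entries],
         "start": [s for _, s, _ in entries],
         "end": [e for _, _, e in entries],
         "strand": ["+"] * len(entries)},
        index=pd.Index([f"M{i}" for i in range(len(entries))],
                       name="probe_id"))


class TestCisCandidates:
    LNC = _annot_row("chr1", 1_000_000, 1_005_000)

    def test_window_boundary_gaps(self):
        # gaps 299999 / 300000 / 300001 around the lncRNA end
        mrnas = _mrna_table([
            ("chr1", 1_305_000, 1_306_000),   # gap 299999
            ("chr1", 1_305_001, 1_306_001),   # gap 300000
            ("chr1", 1_305_002, 1_306_002),   # gap 300001
        ])
        cand = cis_candidates(self.LNC, mrnas, window=300_000)
        assert set(cand["mrna_id"]) == {"M0", "M1"}
        assert dict(zip(cand["mrna_id"], cand["gap"])) == \
            {"M0": 299_999, "M1": 300_000}

    def test_upstream_window_symmetric(self):
        mrnas = _mrna_table([("chr1", 500_000, 699_999),   # gap 300000 upstream
                             ("chr1", 500_000, 699_998)])  # gap 300001
        cand = cis_candidates(self.LNC, mrnas, window=300_000)
        assert set(cand["mrna_id"]) == {"M0"}

    def test_overlap_always_candidate(self):
        mrnas = _mrna_table([("chr1", 1_004_000, 1_010_000)])
        cand = cis_candidates(self.LNC, mrnas, window=0)
        assert cand["gap"].tolist() == [OVERLAP]

    def test_other_chromosome_never_candidate(self):
        mrnas = _mrna_table([("chr2", 1_000_000, 1_005_000)])
        assert cis_candidates(self.LNC, mrnas, window=10**9).empty

    @given(st.integers(1, 10**7), st.integers(1, 10**4),
           st.integers(1, 10**7), st.integers(1, 10**4))
    def test_gap_is_symmetric(self, s1, l1, s2, l2):
        a = interval_gap(s1, s1 + l1, s2, s2 + l2)
        b = interval_gap(s2, s2 + l2, s1, s1 + l1)
        assert a == b


class TestCallCisPairs:
    def _candidates(self):
        return pd.DataFrame({
            "lncrna_id": ["L1", "L1", "L1"],
            "mrna_id": ["M1", "M2", "M3"],
            "chrom": ["chr1"] * 3,
            "gap": [100, 200, 300]})

    def test_p_gate_and_sign(self):
        edges = pd.DataFrame({
            "lncrna_id": ["L1"] * 3, "mrna_id": ["M1", "M2", "M3"],
            "r": [0.9, -0.85, 0.2],
            "p_value": [0.01, 0.05, 0.4],
            "q_value": [0.02, 0.06, 0.5], "n": 12,
            "passes": [True, True, False]})
        pairs = call_cis_pairs(self._candidates(), edges)
        assert set(pairs["mrna_id"]) == {"M1", "M2"}  # p <= 0.05 inclusive
        signs = dict(zip(pairs["mrna_id"], pairs["sign"]))
        assert signs == {"M1": "positive", "M2": "negative"}

    def test_candidate_without_edge_skipped(self, caplog):
        edges = pd.DataFrame({
            "lncrna_id": ["L1"], "mrna_id": ["M1"], "r": [0.9],
            "p_value": [0.01], "q_value": [0.02], "n": 12, "passes": [True]})
        with caplog.at_level("WARNING"):
            pairs = call_cis_pairs(self._candidates(), edges)
        assert len(pairs) == 1
        assert "lack an expression edge" in caplog.text


def _tf_fixture():
    universe = {f"g{i}" for i in range(100)}
    tf_sets = GeneSetCollection(
        {"TF_hit": ("d", frozenset(f"g{i}" for i in range(20))),
         "TF_miss": ("d", frozenset(f"g{i}" for i in range(50, 70)))},
        frozenset(universe))
    mrnas = [f"M{i}" for i in range(10)]
    annot = pd.DataFrame(
        {"gene_symbol": [f"g{i}" for i in range(10)],
         "biotype": ["mRNA"] * 10, "chrom": ["c"] * 10,
         "start": [1] * 10, "end": [9] * 10, "strand": ["+"] * 10},
        index=pd.Index(mrnas, name="probe_id"))
    edges = pd.DataFrame({
        "lncrna_id": ["L1"] * 10, "mrna_id": mrnas,
        "r": [0.9] * 10, "p_value": [0.001] * 10, "q_value": [0.01] * 10,
        "n": 12, "passes": [True] * 8 + [False] * 2})
    return edges, annot, tf_sets


class TestTfAssociations:
    def test_strong_overlap_reported(self):
        edges, annot, tf_sets = _tf_fixture()
        assoc = tf_associations(edges, annot, tf_sets)
        assert assoc.iloc[0]["tf_id"] == "TF_hit"
        assert assoc.iloc[0]["p_value"] < 1e-3
        assert "TF_miss" not in set(assoc["tf_id"])  # overlap 0 -> p = 1

    def test_agrees_with_enrich_set_composition(self):
        edges, annot, tf_sets = _tf_fixture()
        assoc = tf_associations(edges, annot, tf_sets)
        genes = set(annot.loc[edges.loc[edges["passes"], "mrna_id"],
                              "gene_symbol"])
        reference = enrich_set(genes, tf_sets).set_index("set_id")
        for _, row in assoc.iterrows():
            ref = reference.loc[row["tf_id"]]
            assert (row["k"], row["n"], row["K"], row["N"]) == \
                (ref["k"], ref["n"], ref["K"], ref["N"])
            assert row["p_value"] == pytest.approx(ref["p_value"], rel=1e-12)

    def test_de_restriction_shrinks_gene_set(self):
        edges, annot, tf_sets = _tf_fixture()
        assoc = tf_associations(edges, annot, tf_sets,
                                de_genes={"g0", "g1", "g2"})
        assert (assoc["n"] == 3).all()


class TestTriNetwork:
    def _build(self, candidates):
        tf_sets = GeneSetCollection(
            {"TF1": ("d", frozenset({"gA", "gB", "gC", "gZ"})),
             "TF2": ("d", frozenset({"gA", "gQ"}))},
            frozenset({"gA", "gB", "gC", "gZ", "gQ", "gR"}))
        assoc = pd.DataFrame({
            "tf_id": ["TF1", "TF2"], "lncrna_id": ["L1", "L1"],
            "k": [3, 1], "n": [3, 3], "K": [4, 2], "N": [6, 6],
            "p_value": [0.01, 0.04], "q_value": [0.02, 0.04],
            "ratio": [1.5, 1.0]})
        return build_tri_network(assoc, tf_sets, candidates)

    def test_counting_single_association(self):
        tf_sets = GeneSetCollection(
            {"TF1": ("d", frozenset({"gA", "gB", "gC", "gZ"}))},
            frozenset({"gA", "gB", "gC", "gZ"}))
        assoc = pd.DataFrame({
            "tf_id": ["TF1"], "lncrna_id": ["L1"], "k": [3], "n": [3],
            "K": [4], "N": [4], "p_value": [0.01], "q_value": [0.01],
            "ratio": [1.0]})
        net = build_tri_network(assoc, tf_sets, {"L1": ["gA", "gB", "gC"]})
        assert len(net.nodes) == 5     # TF + lncRNA + 3 targets
        assert len(net.edges) == 7     # 1 tf_lncrna + 3 lncrna_target + 3 tf_target

    def test_shared_target_deduplicated(self):
        net = self._build({"L1": ["gA"]})
        assert (net.nodes["id"] == "gA").sum() == 1
        tf_target = net.edges[net.edges["relation"] == "tf_target"]
        assert len(tf_target) == 2  # TF1->gA and TF2->gA

    def test_dangling_edges_rejected(self):
        with pytest.raises(ValueError):
            TriNetwork(pd.DataFrame({"id": ["a"], "role": ["TF"]}),
                       pd.DataFrame({"source": ["a"], "relation": ["tf_target"],
                                     "target": ["ghost"]}))


class TestExportNetwork:
    def test_sif_line_count_and_round_trip(self, tmp_path):
        tf_sets = GeneSetCollection(
            {"TF1": ("d", frozenset({"gA", "gB", "gC"}))}, frozenset({"gA", "gB", "gC"}))
        assoc = pd.DataFrame({
            "tf_id": ["TF1"], "lncrna_id": ["L1"], "k": [3], "n": [3],
            "K": [3], "N": [3], "p_value": [0.01], "q_value": [0.01],
            "ratio": [1.0]})
        net = build_tri_network(assoc, tf_sets, {"L1": ["gA", "gB", "gC"]})
        files = export_network(net, tmp_path / "net")
        assert len(files["sif"].read_text().splitlines()) == 7
        reloaded = load_network(tmp_path / "net")
        export_network(reloaded, tmp_path / "net2")
        assert (tmp_path / "net2.sif").read_bytes() == \
            files["sif"].read_bytes()
        assert (tmp_path / "net2.nodes.tsv").read_bytes() == \
            files["nodes"].read_bytes()

    def test_empty_network(self, tmp_path):
        net = build_tri_network(
            pd.DataFrame(columns=["tf_id", "lncrna_id", "k", "n", "K", "N",
                                  "p_value", "q_value", "ratio"]),
            GeneSetCollection({}, frozenset({"g"})), {})
        files = export_network(net, tmp_path / "net")
        assert files["sif"].read_text() == ""
        assert files["nodes"].read_text().splitlines() == ["id\trole"]
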