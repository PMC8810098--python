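"""Cis (300-kb window) and trans (TF target-set) regulation, network export.

Cis: an mRNA is a candidate neighbour of a lncRNA when both sit on the
same chromosome and the gap between their intervals -- bases strictly
between them, -1 for overlap -- is at most the window (boundary
inclusive; strand ignored).  A candidate becomes a called cis pair when
its expression correlation has raw p <= 0.05, with the sign of r giving
positive/negative cis regulation.

Trans: each lncRNA's passing co-expressed mRNA genes are tested against
every transcription-factor target set by the exact hypergeometric tail;
associations at p <= 0.05 feed the lncRNA-TF-target tri-network, whose
target nodes are the intersection of the TF's targets with that lncRNA's
top co-expressed differential mRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .config import AnalysisConfig
from .data_model import GeneSetCollection
from .enrichment import enrich_set

log = logging.getLogger(__name__)

CIS_COLUMNS = ["lncrna_id", "mrna_id", "chrom", "gap", "r", "p_value", "sign"]
ASSOCIATION_COLUMNS = ["tf_id", "lncrna_id", "k", "n", "K", "N", "p_value",
                       "q_value", "ratio"]

#: Gap sentinel for overlapping intervals (always within any window).
OVERLAP = -1

ROLE_PRIORITY = {"TF": 0, "lncRNA": 1, "target": 2}
RELATIONS = ("tf_lncrna", "lncrna_target", "tf_target")


def interval_gap(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Bases strictly between two 1-based inclusive intervals; -1 if they overlap."""
    if start_b > end_a:
        return start_b - end_a - 1
    if start_a > end_b:
        return start_a - end_b - 1
    return OVERLAP


def cis_candidates(lncrna: pd.Series, mrnas: pd.DataFrame,
                   window: int = 300_000) -> pd.DataFrame:
    """mRNA probes within ``window`` bp of a lncRNA's interval.

    ``lncrna`` is one annotation record (needs chrom/start/end);
    ``mrnas`` is an annotation table indexed by probe id.  Candidacy is
    gap <= window with overlap always a candidate; the window boundary is
    inclusive, so a gap of exactly ``window`` still qualifies.
    """
    same = mrnas[mrnas["chrom"] == lncrna["chrom"]]
    rows = []
    for probe_id, row in same.iterrows():
        gap = interval_gap(int(lncrna["start"]), int(lncrna["end"]),
                           int(row["start"]), int(row["end"]))
        if gap <= window:
            rows.append((probe_id, str(row["chrom"]), gap))
    return pd.DataFrame(rows, columns=["mrna_id", "chrom", "gap"])


def call_cis_pairs(candidates: pd.DataFrame, edges: pd.DataFrame,
                   config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Gate cis candidates on expression-correlation significance.

    ``candidates`` needs columns lncrna_id, mrna_id, chrom, gap (one row
    per window candidate, possibly pooled over lncRNAs).  The gate is the
    raw Pearson p (<= cis_p_threshold), independent of the co-expression
    module's adjust mode.  Candidates without an expression edge are
    skipped with a logged count.
    """
    config = config or AnalysisConfig()
    merged = candidates.merge(
        edges[["lncrna_id", "mrna_id", "r", "p_value"]],
        on=["lncrna_id", "mrna_id"], how="left")
    missing = merged["r"].isna()
    if missing.any():
        log.warning("call_cis_pairs: %d candidate pair(s) lack an expression "
                    "edge", int(missing.sum()))
        merged = merged[~missing]
    called = merged[merged["p_value"] <= config.cis_p_threshold].copy()
    called["sign"] = called["r"].map(lambda r: "positive" if r > 0 else "negative")
    return called.sort_values(["lncrna_id", "mrna_id"], kind="mergesort",
                              ignore_index=True)[CIS_COLUMNS]


def tf_associations(edges: pd.DataFrame, annot: pd.DataFrame,
                    tf_sets: GeneSetCollection,
                    config: AnalysisConfig | None = None,
                    de_genes: set[str] | None = None) -> pd.DataFrame:
    """Hypergeometric lncRNA-TF associations over co-expressed mRNA genes.

    For each lncRNA in ``edges`` the passing co-expressed mRNA gene set
    (optionally intersected with ``de_genes``, the differential mRNA
    symbols) is tested against every TF target set via
    :func:`lncnet.enrichment.enrich_set`; associations with
    p <= tf_p_threshold are returned sorted by ascending p.
    """
    config = config or AnalysisConfig()
    passing = edges[edges["passes"]] if len(edges) else edges
    rows = []
    if passing.empty:
        return pd.DataFrame(columns=ASSOCIATION_COLUMNS)
    for lnc_id, fam in passing.groupby("lncrna_id", sort=True):
        genes = set(annot.loc[[m for m in fam["mrna_id"] if m in annot.index],
                              "gene_symbol"])
        if de_genes is not None:
            genes &= de_genes
        if not genes:
            log.warning("tf_associations: lncRNA %s has an empty co-expressed "
                        "gene set; skipped", lnc_id)
            continue
        records = enrich_set(genes, tf_sets, config.tf_p_threshold)
        hits = records[records["p_value"] <= config.tf_p_threshold]
        for _, row in hits.iterrows():
            rows.append((row["set_id"], lnc_id, row["k"], row["n"], row["K"],
                         row["N"], row["p_value"], row["q_value"], row["ratio"]))
    out = pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS)
    return out.sort_values(["p_value", "tf_id", "lncrna_id"], kind="mergesort",
                           ignore_index=True)


@dataclass
class TriNetwork:
    """lncRNA-TF-target three-element network as flat node/edge tables."""

    nodes: pd.DataFrame  # id, role in {lncRNA, TF, target}
    edges: pd.DataFrame  # source, relation, target

    def __post_init__(self) -> None:
        ids = set(self.nodes["id"])
        dangling = (set(self.edges["source"]) | set(self.edges["target"])) - ids
        if dangling:
            raise ValueError(f"edges reference unknown nodes: {sorted(dangling)[:5]}")


def build_tri_network(associations: pd.DataFrame,
                      tf_sets: GeneSetCollection,
                      candidate_genes: Mapping[str, Sequence[str]],
                      ) -> TriNetwork:
    """Assemble the TF-lncRNA-target network from trans associations.

    ``candidate_genes`` maps each lncRNA to its candidate target genes
    (the pipeline uses the top co-expressed differential mRNAs).  Per
    association the targets are the intersection of the TF's target set
    with the lncRNA's candidates; edges are tf_lncrna per association,
    lncrna_target per lncRNA-candidate pair and tf_target per TF-candidate
    membership, duplicates collapsed.
    """
    node_roles: dict[str, str] = {}
    edge_set: set[tuple[str, str, str]] = set()

    def add_node(node_id: str, role: str) -> None:
        prev = node_roles.get(node_id)
        if prev is None or ROLE_PRIORITY[role] < ROLE_PRIORITY[prev]:
            node_roles[node_id] = role

    any_target = False
    for _, assoc in associations.iterrows():
        tf, lnc = str(assoc["tf_id"]), str(assoc["lncrna_id"])
        add_node(tf, "TF")
        add_node(lnc, "lncRNA")
        edge_set.add((tf, "tf_lncrna", lnc))
        targets = set(tf_sets.members(tf)) & set(candidate_genes.get(lnc, ()))
        for gene in targets:
            any_target = True
            add_node(gene, "target")
            edge_set.add((lnc, "lncrna_target", gene))
            edge_set.add((tf, "tf_target", gene))
    if len(associations) and not any_target:
        log.warning("build_tri_network: no TF target set intersects any "
                    "candidate gene list")
    nodes = pd.DataFrame(sorted(node_roles.items()), columns=["id", "role"])
    edges = pd.DataFrame(sorted(edge_set), columns=["source", "relation", "target"])
    return TriNetwork(nodes, edges)


def export_network(network: TriNetwork, out_prefix: str | Path) -> dict[str, Path]:
    """Write the network as Cytoscape-ingestible SIF + attribute TSVs.

    Emits ``<prefix>.sif`` (source, relation, target), ``<prefix>.nodes.tsv``
    (id, role) and ``<prefix>.edges.tsv``, all lexicographically ordered so
    re-exports are byte-identical.
    """
    prefix = Path(out_prefix)
    sif = prefix.with_suffix(".sif")
    nodes_tsv = prefix.parent / (prefix.name + ".nodes.tsv")
    edges_tsv = prefix.parent / (prefix.name + ".edges.tsv")
    edges = network.edges.sort_values(["source", "relation", "target"],
                                      kind="mergesort", ignore_index=True)
    with open(sif, "w", encoding="utf-8", newline="\n") as fh:
        for _, row in edges.iterrows():
            fh.write(f"{row['source']}\t{row['relation']}\t{row['target']}\n")
    network.nodes.sort_values(["id"], kind="mergesort").to_csv(
        nodes_tsv, sep="\t", index=False, lineterminator="\n")
    edges.to_csv(edges_tsv, sep="\t", index=False, lineterminator="\n")
    return {"sif": sif, "nodes": nodes_tsv, "edges": edges_tsv}


def load_network(out_prefix: str | Path) -> TriNetwork:
    """Reload a network previously written by :func:`export_network`."""
    prefix = Path(out_prefix)
    nodes = pd.read_csv(prefix.parent / (prefix.name + ".nodes.tsv"), sep="\t",
                        dtype=str).fillna("")
    edges = pd.read_csv(prefix.parent / (prefix.name + ".edges.tsv"), sep="\t",
                        dtype=str).fillna("")
    return TriNetwork(nodes, edges)
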