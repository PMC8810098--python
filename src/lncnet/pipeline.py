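"""End-to-end orchestration: de -> coexpress -> function -> cis -> trans -> network.

Every stage writes a TSV under the output directory; a JSON manifest
recording the config, input digests, stage timings and the output
inventory is written last, once all listed files exist.  With a fixed
config and fixed inputs the outputs are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .coexpression import EDGE_COLUMNS, build_edges, top_correlates
from .config import AnalysisConfig
from .data_model import (LNCRNA, MRNA, ExpressionMatrix, GeneSetCollection,
                         load_expression, load_gene_sets,
                         load_probe_annotation, validate_dataset)
from .differential import DIFFERENTIAL_COLUMNS, call_differential
from .enrichment import predict_lncrna_functions
from .regulation import (CIS_COLUMNS, build_tri_network, call_cis_pairs,
                         cis_candidates, export_network, tf_associations)

log = logging.getLogger(__name__)

STAGES = ("de", "coexpress", "function", "cis", "trans", "network")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n",
              float_format="%.10g")


def selected_ids(de_table: pd.DataFrame, biotype: str) -> list[str]:
    """Probe ids selected as differential for one biotype, in table order."""
    mask = de_table["selected"] & (de_table["biotype"] == biotype)
    return de_table.loc[mask, "probe_id"].tolist()


def candidate_target_genes(edges: pd.DataFrame, de_table: pd.DataFrame,
                           annot: pd.DataFrame, config: AnalysisConfig,
                           ) -> dict[str, list[str]]:
    """Per lncRNA: gene symbols of its top co-expressed differential mRNAs.

    These are the candidate target genes of the tri-network: the
    ``top_correlates`` strongest passing co-expression partners of each
    lncRNA, restricted to differential mRNA probes.
    """
    de_mrna = set(selected_ids(de_table, MRNA))
    restricted = edges[edges["passes"] & edges["mrna_id"].isin(de_mrna)]
    out: dict[str, list[str]] = {}
    for lnc_id in restricted["lncrna_id"].unique():
        probes = top_correlates(restricted, lnc_id, config.top_correlates)
        seen: list[str] = []
        for p in probes:
            g = annot.at[p, "gene_symbol"]
            if g not in seen:
                seen.append(g)
        out[lnc_id] = seen
    return out


def run_stages(matrix: ExpressionMatrix, annot: pd.DataFrame,
               terms: GeneSetCollection, tf_sets: GeneSetCollection,
               config: AnalysisConfig, out_dir: str | Path) -> dict:
    """Run all six analysis stages on loaded inputs; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    outputs: dict[str, str] = {}

    def stage(name):
        log.info("stage %s", name)
        timings[name] = time.perf_counter()
        return name

    def done(name, **files):
        timings[name] = round(time.perf_counter() - timings[name], 4)
        outputs.update({k: str(v) for k, v in files.items()})

    report = validate_dataset(matrix, annot)
    matrix = matrix.subset(report.analysis_probes)

    stage("de")
    de_table = call_differential(matrix, annot, config)
    _write(de_table[DIFFERENTIAL_COLUMNS], out / "de.tsv")
    done("de", de=out / "de.tsv")

    stage("coexpress")
    dels = selected_ids(de_table, LNCRNA)
    edges = build_edges(dels, matrix, annot, config)
    _write(edges[EDGE_COLUMNS] if len(edges) else edges, out / "edges.tsv")
    done("coexpress", edges=out / "edges.tsv")

    stage("function")
    prediction = predict_lncrna_functions(edges, annot, terms, config)
    _write(prediction.pairs, out / "prediction_pairs.tsv")
    top = pd.DataFrame({"set_id": prediction.top_terms,
                        "frequency": [prediction.term_frequency[t]
                                      for t in prediction.top_terms]})
    _write(top, out / "top_terms.tsv")
    done("function", prediction_pairs=out / "prediction_pairs.tsv",
         top_terms=out / "top_terms.tsv")

    stage("cis")
    mrna_annot = annot[annot["biotype"] == MRNA]
    chunks = []
    for lnc_id in dels:
        cand = cis_candidates(annot.loc[lnc_id], mrna_annot, config.cis_window)
        if len(cand):
            cand.insert(0, "lncrna_id", lnc_id)
            chunks.append(cand)
    candidates = pd.concat(chunks, ignore_index=True) if chunks else \
        pd.DataFrame(columns=["lncrna_id", "mrna_id", "chrom", "gap"])
    cis_pairs = call_cis_pairs(candidates, edges, config) if len(candidates) \
        else pd.DataFrame(columns=CIS_COLUMNS)
    _write(cis_pairs, out / "cis_pairs.tsv")
    done("cis", cis_pairs=out / "cis_pairs.tsv")

    stage("trans")
    de_genes = set(annot.loc[selected_ids(de_table, MRNA), "gene_symbol"]) \
        if config.trans_restrict_to_de else None
    associations = tf_associations(edges, annot, tf_sets, config, de_genes)
    _write(associations, out / "tf_associations.tsv")
    done("trans", tf_associations=out / "tf_associations.tsv")

    stage("network")
    candidates_map = candidate_target_genes(edges, de_table, annot, config)
    network = build_tri_network(associations, tf_sets, candidates_map)
    files = export_network(network, out / "network")
    done("network", **{f"network_{k}": v for k, v in files.items()})

    manifest = {
        "tool": "lncnet",
        "version": __version__,
        "seed": config.seed,
        "config": config.asdict(),
        "stage_seconds": timings,
        "outputs": outputs,
    }
    return manifest


def run_pipeline(config: AnalysisConfig, expr: str | Path, samples: str | Path,
                 annot_path: str | Path, terms_path: str | Path,
                 tf_path: str | Path, out_dir: str | Path) -> dict:
    """Load inputs from disk, run all stages, write outputs and manifest.json."""
    matrix = load_expression(expr, samples)
    annot = load_probe_annotation(annot_path)
    report = validate_dataset(matrix, annot)
    universe = set(annot.loc[[p for p in report.analysis_probes
                              if annot.at[p, "biotype"] == MRNA],
                             "gene_symbol"])
    terms = load_gene_sets(terms_path, universe,
                           min_size=config.min_term_size,
                           max_size=config.max_term_size)
    tf_sets = load_gene_sets(tf_path, universe)
    manifest = run_stages(matrix, annot, terms, tf_sets, config, out_dir)
    manifest["inputs"] = {str(p): _sha256(p)
                          for p in (expr, samples, annot_path, terms_path, tf_path)}
    out = Path(out_dir)
    for path in manifest["outputs"].values():
        if not Path(path).exists():  # pragma: no cover - defensive
            raise RuntimeError(f"stage output missing at manifest time: {path}")
    with open(out / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
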