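"""Synthetic two-group expression studies with known ground truth.

The generator emulates the study design the pipeline targets: 6 case vs
6 control samples, thousands of mRNA and lncRNA probes with lognormal
intensities (Gaussian on the log2 scale), planted additive fold-change
effects, lncRNA-hub correlation modules built from shared latent factors,
lncRNA-mRNA cis pairs at exactly controlled genomic gaps, and
transcription-factor / functional-term gene sets that overlap the planted
modules.  Every planted structure is recorded in a truth table so
recovery can be scored.

Module construction: the hub lncRNA's noise is the latent factor z and
each member's noise is rho*z + sqrt(1-rho^2)*eps, so the expected
hub-member Pearson correlation is rho and member-member is rho^2.  Cis
pairs use the same construction with a signed rho.

All randomness flows from numpy Generators seeded from ``config.seed``;
identical configs produce byte-identical fixture bundles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .data_model import (ANNOTATION_COLUMNS, LNCRNA, MRNA, ExpressionMatrix,
                         GeneSetCollection, write_gene_sets,
                         write_probe_annotation)
from .errors import ConfigError

PROBE_LENGTH = 2_000          # bp footprint of every synthetic locus
BACKGROUND_SPACING = 700_000  # > 2 x 300-kb window, so background pairs never qualify


def _mrna_probe(i: int) -> str:
    return f"M{i:05d}"


def _mrna_gene(i: int) -> str:
    return f"GENE{i:05d}"


def _lnc_probe(i: int) -> str:
    return f"L{i:05d}"


def _lnc_gene(i: int) -> str:
    return f"LNC{i:05d}"


@dataclass
class SimulationConfig:
    """Shape and effect sizes of a synthetic study.

    ``module_spec`` entries are (hub count, mRNA members per hub, rho):
    each hub lncRNA heads its own correlation module.  ``cis_spec``
    entries are (gap bp, rho) with gap = bases strictly between the
    lncRNA and mRNA intervals (-1 encodes overlap).  ``tf_spec`` and
    ``term_spec`` entries are (set size, overlap fraction with a module),
    wired to modules cyclically; background sets are uniform draws.
    """

    n_case: int = 6
    n_control: int = 6
    n_mrna: int = 2000
    n_lncrna: int = 600
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.5
    de_fraction: float = 0.2
    de_log2fc: float = 1.5
    module_spec: Sequence[tuple[int, int, float]] = ((2, 40, 0.9),)
    cis_spec: Sequence[tuple[int, float]] = (
        (250_000, 0.9), (50_000, -0.9),
        (299_999, 0.8), (300_000, 0.8), (300_001, 0.8))
    tf_spec: Sequence[tuple[int, float]] = ((40, 0.8),)
    n_background_tf: int = 20
    background_tf_size: int = 40
    term_spec: Sequence[tuple[int, float]] = ((40, 0.8), (60, 0.5))
    n_background_terms: int = 50
    background_term_size: int = 40
    plant_de_on_structures: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_case", "n_control", "n_mrna", "n_lncrna"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_case < 2 or self.n_control < 2:
            raise ConfigError("each group needs >= 2 samples")
        if not 0 <= self.de_fraction <= 1:
            raise ConfigError("de_fraction must lie in [0, 1]")
        if self.noise_sd <= 0 or self.baseline_sd < 0:
            raise ConfigError("noise_sd must be > 0 and baseline_sd >= 0")
        for n_hubs, members, rho in self.module_spec:
            if n_hubs < 1 or members < 1:
                raise ConfigError("module counts must be >= 1")
            if not -1 < rho < 1:
                raise ConfigError(f"module rho must lie in (-1, 1), got {rho}")
        for gap, rho in self.cis_spec:
            if gap < -1:
                raise ConfigError(f"cis gap must be >= 0 or the overlap "
                                  f"sentinel -1, got {gap}")
            if not -1 < rho < 1:
                raise ConfigError(f"cis rho must lie in (-1, 1), got {rho}")
        for spec_name in ("tf_spec", "term_spec"):
            for size, frac in getattr(self, spec_name):
                if size < 1:
                    raise ConfigError(f"{spec_name} set size must be >= 1")
                if not 0 <= frac <= 1:
                    raise ConfigError(f"{spec_name} overlap fraction must lie "
                                      f"in [0, 1]")
        layout = _Layout(self)  # raises ConfigError if specs exceed probes
        del layout

    def asdict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("module_spec", "cis_spec", "tf_spec", "term_spec"):
            d[key] = [list(t) for t in d[key]]
        return d


class _Layout:
    """Deterministic allocation of probes to planted structures.

    lncRNA probes: module hubs first, then cis lncRNAs, then free.
    mRNA probes: module members first, then cis mRNAs, then free.
    """

    def __init__(self, config: SimulationConfig) -> None:
        self.config = config
        self.modules: list[dict] = []   # module_id, hub (lnc idx), members (mrna idx), rho
        lnc_cursor = 0
        mrna_cursor = 0
        module_no = 0
        for n_hubs, members, rho in config.module_spec:
            for _ in range(n_hubs):
                module_no += 1
                self.modules.append({
                    "module_id": f"module{module_no}",
                    "hub": lnc_cursor,
                    "members": list(range(mrna_cursor, mrna_cursor + members)),
                    "rho": rho,
                })
                lnc_cursor += 1
                mrna_cursor += members
        self.cis: list[dict] = []       # lnc idx, mrna idx, gap, rho
        for gap, rho in config.cis_spec:
            self.cis.append({"lnc": lnc_cursor, "mrna": mrna_cursor,
                             "gap": gap, "rho": rho})
            lnc_cursor += 1
            mrna_cursor += 1
        if lnc_cursor > config.n_lncrna:
            raise ConfigError(f"module/cis specs need {lnc_cursor} lncRNA "
                              f"probes, only {config.n_lncrna} available")
        if mrna_cursor > config.n_mrna:
            raise ConfigError(f"module/cis specs need {mrna_cursor} mRNA "
                              f"probes, only {config.n_mrna} available")
        self.free_lnc = list(range(lnc_cursor, config.n_lncrna))
        self.free_mrna = list(range(mrna_cursor, config.n_mrna))


@dataclass
class TruthTable:
    """Ground truth of every planted structure in a fixture."""

    de: pd.DataFrame          # probe_id, direction, log2fc
    modules: pd.DataFrame     # module_id, hub_probe, member_probe, member_gene, rho
    cis: pd.DataFrame         # lncrna_id, mrna_id, gap, rho, sign
    tf: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["tf_id", "module_id", "overlap_fraction", "planted"]))
    terms: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["set_id", "module_id", "overlap_fraction", "planted"]))

    @property
    def de_probes(self) -> set[str]:
        return set(self.de["probe_id"])

    def hub_probes(self) -> list[str]:
        return sorted(set(self.modules["hub_probe"]))


def _probe_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    mrna = [_mrna_probe(i) for i in range(config.n_mrna)]
    lnc = [_lnc_probe(i) for i in range(config.n_lncrna)]
    return mrna, lnc


def simulate_expression(config: SimulationConfig,
                        ) -> tuple[ExpressionMatrix, TruthTable]:
    """Draw one expression matrix with planted effects plus its truth table.

    Baseline per-probe means are Normal(baseline_mean, baseline_sd^2);
    per-sample noise is Normal(0, noise_sd^2) with the latent-factor
    structure described in the module docstring; differential probes get
    +/- de_log2fc added to the case samples.  With
    ``plant_de_on_structures`` the hub lncRNAs, module members and cis
    probes are themselves differential (sign following the planted
    correlation), which is what makes them discoverable by the full
    pipeline; the planted-correlation calibration is exact with the flag
    off.
    """
    layout = _Layout(config)
    rng = np.random.default_rng([config.seed, 0])
    mrna_ids, lnc_ids = _probe_ids(config)
    probe_ids = mrna_ids + lnc_ids
    n_probes = len(probe_ids)
    n_samples = config.n_case + config.n_control
    lnc_offset = config.n_mrna

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n_probes)
    noise = rng.standard_normal((n_probes, n_samples))
    for mod in layout.modules:
        z = rng.standard_normal(n_samples)
        noise[lnc_offset + mod["hub"]] = z
        rho = mod["rho"]
        mix = np.sqrt(1.0 - rho * rho)
        for m in mod["members"]:
            noise[m] = rho * z + mix * noise[m]
    for pair in layout.cis:
        z = rng.standard_normal(n_samples)
        noise[lnc_offset + pair["lnc"]] = z
        rho = pair["rho"]
        noise[pair["mrna"]] = rho * z + np.sqrt(1.0 - rho * rho) * noise[pair["mrna"]]

    values = baseline[:, None] + config.noise_sd * noise

    # planted differential effects: (row index, signed log2 shift)
    de_entries: list[tuple[int, float]] = []
    if config.plant_de_on_structures:
        for mod in layout.modules:
            de_entries.append((lnc_offset + mod["hub"], config.de_log2fc))
            de_entries.extend((m, config.de_log2fc) for m in mod["members"])
        for pair in layout.cis:
            de_entries.append((lnc_offset + pair["lnc"], config.de_log2fc))
            sign = 1.0 if pair["rho"] >= 0 else -1.0
            de_entries.append((pair["mrna"], sign * config.de_log2fc))
    for free, offset in ((layout.free_mrna, 0), (layout.free_lnc, lnc_offset)):
        n_de = int(round(config.de_fraction * len(free)))
        chosen = rng.choice(free, size=n_de, replace=False) if n_de else []
        for j, idx in enumerate(sorted(int(i) for i in np.asarray(chosen))):
            shift = config.de_log2fc if j < (n_de + 1) // 2 else -config.de_log2fc
            de_entries.append((offset + idx, shift))

    case_cols = np.arange(config.n_case)
    for row, shift in de_entries:
        values[row, case_cols] += shift

    sample_ids = [f"case_{i + 1}" for i in range(config.n_case)] + \
        [f"control_{i + 1}" for i in range(config.n_control)]
    groups = pd.Series(["case"] * config.n_case + ["control"] * config.n_control,
                       index=sample_ids)
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=probe_ids, columns=sample_ids), groups)

    de = pd.DataFrame(
        [(probe_ids[row], "up" if shift > 0 else "down", shift)
         for row, shift in sorted(de_entries)],
        columns=["probe_id", "direction", "log2fc"])
    modules = pd.DataFrame(
        [(mod["module_id"], _lnc_probe(mod["hub"]), _mrna_probe(m),
          _mrna_gene(m), mod["rho"])
         for mod in layout.modules for m in mod["members"]],
        columns=["module_id", "hub_probe", "member_probe", "member_gene", "rho"])
    cis = pd.DataFrame(
        [(_lnc_probe(p["lnc"]), _mrna_probe(p["mrna"]), p["gap"], p["rho"],
          "positive" if p["rho"] >= 0 else "negative")
         for p in layout.cis],
        columns=["lncrna_id", "mrna_id", "gap", "rho", "sign"])
    return matrix, TruthTable(de=de, modules=modules, cis=cis)


def simulate_genome_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Synthetic probe annotation realizing the configured cis geometry.

    Each cis pair sits alone on its own chromosome with exactly the
    requested gap (``mRNA.start = lncRNA.end + gap + 1``; the -1 sentinel
    nests the mRNA inside the lncRNA interval).  All other probes share a
    background chromosome spaced ``700 kb`` apart, beyond twice the 300-kb
    window, so no unplanted pair is ever a window candidate.
    """
    layout = _Layout(config)
    rng = np.random.default_rng([config.seed, 1])
    coords: dict[str, tuple[str, int, int]] = {}

    for i, pair in enumerate(layout.cis):
        chrom = f"chr_cis{i + 1}"
        lnc_start = 1_000_000
        lnc_end = lnc_start + PROBE_LENGTH - 1
        if pair["gap"] == -1:
            m_start = lnc_start + PROBE_LENGTH // 4
        else:
            m_start = lnc_end + pair["gap"] + 1
        coords[_lnc_probe(pair["lnc"])] = (chrom, lnc_start, lnc_end)
        coords[_mrna_probe(pair["mrna"])] = (chrom, m_start,
                                             m_start + PROBE_LENGTH - 1)

    mrna_ids, lnc_ids = _probe_ids(config)
    background = [p for p in mrna_ids + lnc_ids if p not in coords]
    for i, probe in enumerate(background):
        start = 1 + i * BACKGROUND_SPACING
        coords[probe] = ("chr_bg", start, start + PROBE_LENGTH - 1)

    rows = []
    for i, probe in enumerate(mrna_ids + lnc_ids):
        chrom, start, end = coords[probe]
        symbol = _mrna_gene(i) if i < config.n_mrna else _lnc_gene(i - config.n_mrna)
        biotype = MRNA if i < config.n_mrna else LNCRNA
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((probe, symbol, biotype, chrom, start, end, strand))
    return pd.DataFrame(rows, columns=["probe_id"] + ANNOTATION_COLUMNS
                        ).set_index("probe_id")


def simulate_gene_sets(config: SimulationConfig, truth: TruthTable,
                       ) -> tuple[GeneSetCollection, GeneSetCollection]:
    """Functional-term and TF target-set collections over the mRNA universe.

    Planted sets draw ``overlap_fraction`` of their members from one
    module's mRNA genes (modules assigned cyclically) and the rest
    uniformly from genes outside that module; background sets are uniform
    draws.  Provenance lands in ``truth.terms`` / ``truth.tf``.
    """
    rng = np.random.default_rng([config.seed, 2])
    universe = [_mrna_gene(i) for i in range(config.n_mrna)]
    universe_set = frozenset(universe)
    module_genes: list[tuple[str, list[str]]] = []
    for module_id, grp in truth.modules.groupby("module_id", sort=True):
        module_genes.append((module_id, sorted(grp["member_gene"])))

    def planted_set(size: int, frac: float, which: int) -> tuple[str, list[str]]:
        if frac > 0 and not module_genes:
            raise ConfigError("planted set overlap requested but no modules exist")
        module_id, genes = module_genes[which % len(module_genes)] if \
            module_genes else ("", [])
        n_overlap = int(round(size * frac))
        if n_overlap > len(genes):
            raise ConfigError(f"overlap {n_overlap} exceeds module size "
                              f"{len(genes)}")
        chosen = list(rng.choice(genes, size=n_overlap, replace=False)) if \
            n_overlap else []
        pool = sorted(universe_set - set(genes))
        rest = list(rng.choice(pool, size=size - n_overlap, replace=False))
        return module_id, chosen + rest

    def build(spec, n_background, background_size, prefix):
        sets: dict[str, tuple[str, frozenset[str]]] = {}
        prov = []
        for j, (size, frac) in enumerate(spec):
            set_id = f"{prefix}{j + 1:03d}"
            module_id, members = planted_set(size, frac, j)
            sets[set_id] = ("planted synthetic set", frozenset(members))
            prov.append((set_id, module_id if frac > 0 else "",
                         frac, frac > 0))
        for j in range(n_background):
            set_id = f"{prefix}BG{j + 1:03d}"
            members = rng.choice(universe, size=background_size, replace=False)
            sets[set_id] = ("background synthetic set", frozenset(members))
            prov.append((set_id, "", 0.0, False))
        collection = GeneSetCollection(sets, universe_set)
        prov_df = pd.DataFrame(prov, columns=["set_id", "module_id",
                                              "overlap_fraction", "planted"])
        return collection, prov_df

    terms, truth.terms = build(config.term_spec, config.n_background_terms,
                               config.background_term_size, "TERM")
    tfs, tf_prov = build(config.tf_spec, config.n_background_tf,
                         config.background_tf_size, "TF")
    truth.tf = tf_prov.rename(columns={"set_id": "tf_id"})
    return terms, tfs


def assemble_fixture(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete fixture bundle that loads cleanly through data_model.

    Emits expression.tsv, samples.tsv, annotation.bed, terms.gmt,
    tf_targets.gmt, config.yaml and a truth/ directory of ground-truth
    TSVs; returns the path of every file written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)

    matrix, truth = simulate_expression(config)
    annot = simulate_genome_annotation(config)
    terms, tfs = simulate_gene_sets(config, truth)

    paths = {
        "expression": out / "expression.tsv",
        "samples": out / "samples.tsv",
        "annotation": out / "annotation.bed",
        "terms": out / "terms.gmt",
        "tf_targets": out / "tf_targets.gmt",
        "config": out / "config.yaml",
        "truth_de": truth_dir / "de.tsv",
        "truth_modules": truth_dir / "modules.tsv",
        "truth_cis": truth_dir / "cis.tsv",
        "truth_tf": truth_dir / "tf.tsv",
        "truth_terms": truth_dir / "terms.tsv",
    }
    matrix.write(paths["expression"], paths["samples"])
    write_probe_annotation(annot, paths["annotation"])
    write_gene_sets(terms, paths["terms"])
    write_gene_sets(tfs, paths["tf_targets"])
    with open(paths["config"], "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(config.asdict(), fh, sort_keys=True)
    for key, df in (("truth_de", truth.de), ("truth_modules", truth.modules),
                    ("truth_cis", truth.cis), ("truth_tf", truth.tf),
                    ("truth_terms", truth.terms)):
        df.to_csv(paths[key], sep="\t", index=False, lineterminator="\n")
    return paths
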