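"""Containers and text-format IO: expression TSV, BED6+2 annotation, GMT sets.

The in-memory genomic convention is 1-based, inclusive on both ends.  BED
input (0-based, half-open) is converted once at the loading boundary:
``start = chromStart + 1``, ``end = chromEnd``.  All writers emit UTF-8
with LF line endings so that repeated exports are byte-stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError

log = logging.getLogger(__name__)

MRNA = "mRNA"
LNCRNA = "lncRNA"
BIOTYPES = (MRNA, LNCRNA)
GROUPS = ("case", "control")
STRANDS = ("+", "-", ".")

#: Column order of the in-memory probe annotation table (index: probe_id).
ANNOTATION_COLUMNS = ["gene_symbol", "biotype", "chrom", "start", "end", "strand"]


@dataclass
class ExpressionMatrix:
    """Log2 expression values, probes x samples, with case/control labels.

    ``values`` is a float DataFrame indexed by probe id with sample-id
    columns; ``groups`` maps every sample id to ``"case"`` or ``"control"``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise FormatError(f"duplicate probe id {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise FormatError("expression matrix contains missing or non-finite values")
        self.values = v.astype(float)
        missing = [s for s in v.columns if s not in self.groups.index]
        if missing:
            raise ConsistencyError(f"samples missing from sample sheet: {missing}")
        self.groups = self.groups.reindex(v.columns)
        bad = set(self.groups) - set(GROUPS)
        if bad:
            raise FormatError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
        for g in GROUPS:
            if (self.groups == g).sum() < 2:
                raise ConsistencyError(f"group {g!r} has fewer than 2 samples")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def case_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "case"])

    @property
    def control_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "control"])

    def subset(self, probe_ids: Iterable[str]) -> "ExpressionMatrix":
        """Restrict to the given probes, keeping their given order."""
        return ExpressionMatrix(self.values.loc[list(probe_ids)], self.groups.copy())

    def write(self, expr_path: str | Path, sheet_path: str | Path) -> None:
        df = self.values.copy()
        df.index.name = "probe_id"
        df.to_csv(expr_path, sep="\t", lineterminator="\n", float_format="%.6f")
        sheet = pd.DataFrame({"sample_id": self.sample_ids,
                              "group": self.groups.to_numpy()})
        sheet.to_csv(sheet_path, sep="\t", index=False, lineterminator="\n")


def load_expression(path: str | Path, sample_sheet: str | Path) -> ExpressionMatrix:
    """Read a probes-x-samples log2 expression TSV plus its sample sheet.

    The first column of the matrix must be headed ``probe_id``; the sheet
    needs columns ``sample_id`` and ``group`` with values case/control.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != "probe_id":
        raise FormatError(f"{path}: first column must be headed 'probe_id', "
                          f"got {header[:1]!r}")
    seen: set[str] = set()
    for sid in header[1:]:
        if sid in seen:
            raise FormatError(f"{path}: duplicate sample id {sid!r} in header")
        seen.add(sid)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse expression TSV: {exc}") from exc
    if df.isna().to_numpy().any():
        raise FormatError(f"{path}: missing cells in expression matrix")
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric expression value: {exc}") from exc
    sheet = pd.read_csv(sample_sheet, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in sheet.columns:
            raise FormatError(f"{sample_sheet}: missing column {col!r}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{sample_sheet}: duplicate sample id {dup!r}")
    groups = pd.Series(sheet["group"].to_numpy(), index=sheet["sample_id"].to_numpy())
    return ExpressionMatrix(values, groups)


def load_probe_annotation(path: str | Path) -> pd.DataFrame:
    """Read BED6+2 probe annotation into the 1-based inclusive convention.

    Columns: chrom, chromStart, chromEnd, probe_id, score (ignored), strand,
    gene_symbol, biotype.  Returns a DataFrame indexed by probe_id with
    columns ``gene_symbol, biotype, chrom, start, end, strand``.
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise FormatError(f"{path}:{lineno}: expected 8 BED6+2 columns, "
                                  f"got {len(parts)}")
            chrom, s, e, probe_id, _score, strand, symbol, biotype = parts[:8]
            try:
                chrom_start, chrom_end = int(s), int(e)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if chrom_start >= chrom_end:
                raise FormatError(f"{path}:{lineno}: chromStart {chrom_start} >= "
                                  f"chromEnd {chrom_end}")
            if biotype not in BIOTYPES:
                raise FormatError(f"{path}:{lineno}: biotype {biotype!r} not in "
                                  f"{BIOTYPES}")
            if strand not in STRANDS:
                raise FormatError(f"{path}:{lineno}: strand {strand!r} not in "
                                  f"{STRANDS}")
            rows.append((probe_id, symbol, biotype, chrom,
                         chrom_start + 1, chrom_end, strand))
    annot = pd.DataFrame(rows, columns=["probe_id"] + ANNOTATION_COLUMNS)
    if annot["probe_id"].duplicated().any():
        dup = annot.loc[annot["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise FormatError(f"{path}: duplicate probe id {dup!r}")
    return annot.set_index("probe_id")


def write_probe_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    """Write annotation back to BED6+2 (inverse of :func:`load_probe_annotation`)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for probe_id, row in annot.iterrows():
            fh.write("\t".join([
                str(row["chrom"]), str(int(row["start"]) - 1), str(int(row["end"])),
                str(probe_id), "0", str(row["strand"]),
                str(row["gene_symbol"]), str(row["biotype"]),
            ]) + "\n")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT) restricted to a measured gene universe."""

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for set_id, (_desc, members) in self.sets.items():
            extra = members - self.universe
            if extra:
                raise ConsistencyError(
                    f"set {set_id!r} has members outside the universe: "
                    f"{sorted(extra)[:5]}")
            if not members:
                raise ConsistencyError(f"set {set_id!r} is empty")

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]

    def description(self, set_id: str) -> str:
        return self.sets[set_id][0]

    @property
    def set_ids(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets


def load_gene_sets(path: str | Path, universe: Iterable[str],
                   min_size: int = 1, max_size: int | None = None,
                   ) -> GeneSetCollection:
    """Read a GMT file, intersecting every set with ``universe``.

    Sets that are empty (or outside ``[min_size, max_size]``) after the
    restriction are dropped with a logged count.  Duplicate member symbols
    on one line are stored once.
    """
    universe = frozenset(universe)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    dropped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 columns")
            set_id, desc = parts[0], parts[1]
            if set_id in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            members = frozenset(parts[2:]) & universe
            if not members or len(members) < min_size or \
                    (max_size is not None and len(members) > max_size):
                dropped += 1
                continue
            sets[set_id] = (desc, members)
    if dropped:
        log.warning("%s: dropped %d gene set(s) after universe/size restriction",
                    path, dropped)
    return GeneSetCollection(sets, universe)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection back to GMT with sorted members (byte-stable)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for set_id in collection.set_ids:
            desc, members = collection.sets[set_id]
            fh.write("\t".join([set_id, desc, *sorted(members)]) + "\n")


@dataclass
class ValidationReport:
    """Cross-check of expression matrix against probe annotation."""

    unannotated_probes: list[str]
    unexpressed_probes: list[str]
    n_mrna: int
    n_lncrna: int
    analysis_probes: list[str] = field(repr=False)

    @property
    def n_analysis(self) -> int:
        return len(self.analysis_probes)


def validate_dataset(matrix: ExpressionMatrix, annot: pd.DataFrame) -> ValidationReport:
    """Report probes lacking annotation / expression; fatal if disjoint.

    The downstream analysis set is the annotated intersection, in matrix
    probe order.
    """
    expr_ids = set(matrix.probe_ids)
    annot_ids = set(annot.index)
    analysis = [p for p in matrix.probe_ids if p in annot_ids]
    if not analysis:
        raise ConsistencyError("expression matrix and annotation share no probes")
    biotypes = annot.loc[analysis, "biotype"]
    report = ValidationReport(
        unannotated_probes=sorted(expr_ids - annot_ids),
        unexpressed_probes=sorted(annot_ids - expr_ids),
        n_mrna=int((biotypes == MRNA).sum()),
        n_lncrna=int((biotypes == LNCRNA).sum()),
        analysis_probes=analysis,
    )
    if report.unannotated_probes or report.unexpressed_probes:
        log.warning("validate_dataset: %d unannotated probe(s), %d annotation "
                    "record(s) without expression",
                    len(report.unannotated_probes), len(report.unexpressed_probes))
    return report
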