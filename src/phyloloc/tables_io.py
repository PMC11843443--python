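"""Readers and writers for every external table the pipeline touches.

Dialects: tab-separated gene-age and paralog tables with a header line,
DeepLoc-2.0-style localization CSV, STRING-style physical-link files,
protein FASTA, and GTF annotation (only ``exon`` features are consumed).
Malformed lines abort with a line-numbered error rather than being skipped:
silent skipping would corrupt the counts that downstream statistics divide by.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .vocab import (
    BIOTYPES,
    COMPARTMENTS,
    PLASTID,
    canonical_compartment,
    validate_branch,
)

log = logging.getLogger(__name__)

AGE_TABLE_COLUMNS = ("gene_id", "branch", "biotype", "chromosome")


@dataclass(frozen=True)
class GeneAgeRecord:
    """One dated gene: its origination branch, biotype and chromosome."""

    gene_id: str
    branch: str
    biotype: str
    chromosome: str

    def __post_init__(self) -> None:
        validate_branch(self.branch)
        if self.biotype not in BIOTYPES:
            raise ValueError(
                f"unknown biotype {self.biotype!r}; expected one of {BIOTYPES}"
            )


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as a list of exon intervals (1-based inclusive, GTF)."""

    transcript_id: str
    gene_id: str
    exon_intervals: tuple[tuple[str, int, int, str], ...]

    def __post_init__(self) -> None:
        if not self.exon_intervals:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        prev_end = None
        for chrom, start, end, strand in sorted(
            self.exon_intervals, key=lambda e: (e[0], e[1])
        ):
            if end < start:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon end {end} < start {start}"
                )
            if prev_end is not None and start <= prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
            prev_end = end

    @property
    def length(self) -> int:
        """Summed exon length in nucleotides (1-based inclusive intervals)."""
        return sum(end - start + 1 for _, start, end, _ in self.exon_intervals)


class ParseError(ValueError):
    """A malformed input line, reported with its 1-based line number."""


def read_age_table(path: str | Path) -> list[GeneAgeRecord]:
    """Read a tab-separated gene-age table (header: gene_id, branch, biotype,
    chromosome).  Unknown branch labels and duplicate gene IDs are rejected."""
    records: list[GeneAgeRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header[:4]) != AGE_TABLE_COLUMNS:
            raise ParseError(
                f"{path}: line 1: expected header {AGE_TABLE_COLUMNS}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 fields, got {len(row)}")
            gene_id, branch, biotype, chromosome = row[:4]
            try:
                rec = GeneAgeRecord(gene_id, branch, biotype, chromosome)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if gene_id in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            records.append(rec)
    return records


def write_age_table(records: Iterable[GeneAgeRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(AGE_TABLE_COLUMNS)
        for rec in records:
            writer.writerow([rec.gene_id, rec.branch, rec.biotype, rec.chromosome])


def read_localization_table(path: str | Path) -> pd.DataFrame:
    """Read a DeepLoc-2.0-style CSV of per-compartment probabilities.

    Returns a DataFrame indexed by protein ID with exactly the nine canonical
    compartment columns; a Plastid column, if present, is dropped (it is a
    plant-specific organelle).  Probabilities outside [0, 1] are rejected.
    """
    raw = pd.read_csv(path)
    id_col = raw.columns[0]
    rename: dict[str, str] = {}
    for col in raw.columns[1:]:
        canon = canonical_compartment(col)
        if canon is None:
            raise ParseError(f"{path}: unrecognized column {col!r}")
        rename[col] = canon
    raw = raw.rename(columns=rename)
    if PLASTID in raw.columns:
        raw = raw.drop(columns=[PLASTID])
    missing = [c for c in COMPARTMENTS if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: missing compartment column(s) {missing}")
    table = raw.set_index(id_col)[list(COMPARTMENTS)].astype(float)
    table.index.name = "protein_id"
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate protein ID {dup!r}")
    if ((table < 0) | (table > 1)).any().any():
        bad = table[((table < 0) | (table > 1)).any(axis=1)].index[0]
        raise ParseError(f"{path}: probability outside [0, 1] for protein {bad!r}")
    return table


def write_localization_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table[list(COMPARTMENTS)].copy()
    out.index.name = "Protein_ID"
    out.to_csv(path)


def select_longest_transcript(models: Iterable[TranscriptModel]) -> dict[str, str]:
    """Pick one representative transcript per gene: maximal summed exon
    length, ties broken by lexicographically smallest transcript ID."""
    best: dict[str, TranscriptModel] = {}
    for model in models:
        cur = best.get(model.gene_id)
        if (
            cur is None
            or model.length > cur.length
            or (model.length == cur.length and model.transcript_id < cur.transcript_id)
        ):
            best[model.gene_id] = model
    return {gene: m.transcript_id for gene, m in best.items()}


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf_transcripts(path: str | Path) -> list[TranscriptModel]:
    """Extract transcript models (exon features only) from a GTF file."""
    exons: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 fields, got {len(fields)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            attr = dict(_GTF_ATTR.findall(attrs))
            try:
                gene_id = attr["gene_id"]
                transcript_id = attr["transcript_id"]
            except KeyError as exc:
                raise ParseError(f"{path}: line {lineno}: missing attribute {exc}") from exc
            entry = exons.setdefault(
                transcript_id, {"gene_id": gene_id, "intervals": []}
            )
            entry["intervals"].append((chrom, int(start), int(end), strand))
    return [
        TranscriptModel(tid, entry["gene_id"], tuple(sorted(entry["intervals"])))
        for tid, entry in exons.items()
    ]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein FASTA into an ID -> sequence mapping.

    IDs are the first whitespace token of the header; sequences are
    uppercased with trailing '*' stop characters stripped.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper().rstrip("*")
        if record.id in sequences:
            raise ParseError(f"{path}: duplicate sequence ID {record.id!r}")
        if not seq:
            raise ParseError(f"{path}: empty sequence for {record.id!r}")
        sequences[record.id] = seq
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


PARALOG_TABLE_COLUMNS = ("gene_id", "paralog_gene_id")


def read_paralog_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated paralog pair table (FlyBase-style, two gene
    columns); polarity (parent vs offspring) is assigned downstream from ages."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in PARALOG_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return table[list(PARALOG_TABLE_COLUMNS)]


def write_paralog_table(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs[list(PARALOG_TABLE_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_pathways(path: str | Path) -> dict[str, set[str]]:
    """Read a tab-separated protein -> pathway table (pathway IDs comma-joined
    in the second column), emulating KEGG annotation output."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[0] != "protein_id":
            raise ParseError(f"{path}: line 1: expected header starting with protein_id")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 fields")
            protein, pathways = row[0], row[1]
            if protein in mapping:
                raise ParseError(f"{path}: line {lineno}: duplicate protein {protein!r}")
            mapping[protein] = {p for p in pathways.split(",") if p}
    return mapping


def write_pathways(mapping: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "pathway_ids"])
        for protein, pathways in mapping.items():
            writer.writerow([protein, ",".join(sorted(pathways))])


def read_presence_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x outgroup-clade presence/absence matrix (TSV; first column
    gene_id, remaining columns 0/1 per clade)."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index.name = "gene_id"
    return table.astype(bool)


def write_presence_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.astype(int).to_csv(path, sep="\t")
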