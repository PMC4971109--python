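"""Readers and writers for every external file the pipeline touches.

All tables are tab-separated on write (comma accepted on read), UTF-8 with
Unix newlines.  CDS FASTA entries are one gene per record; the description
after the first whitespace is kept as the product annotation.  Quality
control on CDS records enforces what every downstream formula assumes:
length a multiple of three, no internal frame-0 stop, at most 5% ambiguous
bases.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields, is_dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError
from .genetic_code import standard_code

logger = logging.getLogger(__name__)

MAX_N_FRACTION = 0.05

# anything outside the unambiguous DNA alphabet is treated as N
_NORMALIZE = str.maketrans(
    {c: "N" for c in "RYSWKMBDHVryswkmbdhv"} | {"U": "T", "u": "T"}
)


@dataclass
class GeneRecord:
    """One in-frame CDS with its strain of origin."""

    gene_id: str
    strain_id: str
    sequence: str
    product: str = ""
    is_excluded: bool = False

    @property
    def length_nt(self) -> int:
        return len(self.sequence)


@dataclass
class TRNATable:
    """Anticodon (DNA, 5'->3') -> genomic copy number."""

    entries: dict[str, int]

    def copy_number(self, anticodon: str) -> int:
        return self.entries.get(anticodon.upper().replace("U", "T"), 0)


@dataclass
class ExpressionTable:
    """gene_id -> non-negative abundance; missing genes are absent keys."""

    values: dict[str, float]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.values

    def get(self, gene_id: str, default=None):
        return self.values.get(gene_id, default)


@dataclass
class ClusterTable:
    """cluster_id -> member gene_ids; each gene belongs to at most one cluster."""

    clusters: dict[str, list[str]]

    def __post_init__(self):
        seen: dict[str, str] = {}
        for cid, members in self.clusters.items():
            if not members:
                raise ValidationError(f"cluster {cid!r} has no members")
            for g in members:
                if g in seen:
                    raise ValidationError(
                        f"gene {g!r} appears in clusters {seen[g]!r} and {cid!r}"
                    )
                seen[g] = cid

    @property
    def n_genes(self) -> int:
        return sum(len(m) for m in self.clusters.values())

    def cluster_of(self) -> dict[str, str]:
        return {g: cid for cid, members in self.clusters.items() for g in members}


def qc_failure(sequence: str, code=None) -> str | None:
    """Return the QC failure reason for a CDS, or None if it passes.

    Rules: length a positive multiple of 3; no stop codon in frame 0 before
    the final codon; N fraction at most 5%.
    """
    code = code or standard_code()
    n = len(sequence)
    if n == 0 or n % 3 != 0:
        return f"length {n} is not a positive multiple of 3"
    if sequence.count("N") / n > MAX_N_FRACTION:
        return f"more than {MAX_N_FRACTION:.0%} ambiguous bases"
    for i in range(0, n - 3, 3):
        if sequence[i : i + 3] in code.stop_codons:
            return f"internal stop codon at nt {i + 1}"
    return None


def qc_filter(
    records: Iterable[GeneRecord], qc_policy: str = "skip"
) -> list[GeneRecord]:
    """Drop (or reject, under policy 'error') records failing CDS QC."""
    if qc_policy not in ("skip", "error"):
        raise ValidationError(f"unknown qc_policy {qc_policy!r}")
    kept = []
    for rec in records:
        reason = qc_failure(rec.sequence)
        if reason is None:
            kept.append(rec)
        elif qc_policy == "error":
            raise ValidationError(f"record {rec.gene_id!r} failed QC: {reason}")
        else:
            logger.warning("skipping %s: %s", rec.gene_id, reason)
    return kept


def read_cds_fasta(
    path: str | Path, strain_id: str, qc_policy: str = "skip"
) -> list[GeneRecord]:
    """Read a per-strain CDS multi-FASTA into QC-passing GeneRecords.

    Gene ids are namespaced as ``strain_id + ":" + local_id`` so that the
    same locus tag occurring in several strains stays unique.
    """
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper().translate(_NORMALIZE)
        desc = entry.description.split(None, 1)
        product = desc[1] if len(desc) > 1 else ""
        records.append(
            GeneRecord(
                gene_id=f"{strain_id}:{entry.id}",
                strain_id=strain_id,
                sequence=seq,
                product=product,
            )
        )
    return qc_filter(records, qc_policy=qc_policy)


def write_cds_fasta(records: Iterable[GeneRecord], path: str | Path) -> None:
    """Write GeneRecords as FASTA, local id first, product as description.

    The strain namespace prefix is stripped so that a write/read cycle with
    the same strain_id round-trips gene ids exactly.
    """
    out = []
    for rec in records:
        local = rec.gene_id.split(":", 1)[1] if ":" in rec.gene_id else rec.gene_id
        out.append(SeqRecord(Seq(rec.sequence), id=local, description=rec.product))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        SeqIO.write(out, fh, "fasta")


def _data_lines(path: str | Path) -> list[list[str]]:
    """Split a small delimited file into fields, sniffing tab vs comma."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if "\t" in line:
                fields = line.split("\t")
            elif "," in line:
                fields = line.split(",")
            else:
                fields = line.split()
            rows.append([f.strip() for f in fields])
    return rows


def _parse_copy_number(text: str, where: str) -> int:
    try:
        value = float(text)
    except ValueError:
        raise ValidationError(f"{where}: copy number {text!r} is not a number")
    if value < 0:
        raise ValidationError(f"{where}: negative copy number {text!r}")
    if value != int(value):
        raise ValidationError(f"{where}: copy number {text!r} is not an integer")
    return int(value)


def read_trna_table(path: str | Path) -> TRNATable:
    """Load a two-column (anticodon, copy_number) table; duplicates are summed.

    Anticodons may be RNA or DNA; they are normalized to DNA internally.
    """
    entries: dict[str, int] = {}
    rows = _data_lines(path)
    for i, row in enumerate(rows):
        if len(row) < 2:
            raise ValidationError(f"{path}: row {i + 1} has fewer than 2 columns")
        anticodon = row[0].upper().replace("U", "T")
        is_triplet = len(anticodon) == 3 and all(b in "ACGT" for b in anticodon)
        if i == 0 and not _looks_numeric(row[1]) and not is_triplet:
            continue  # optional header
        if len(anticodon) != 3 or any(b not in "ACGT" for b in anticodon):
            raise ValidationError(
                f"{path}: row {i + 1}: {row[0]!r} is not a valid anticodon triplet"
            )
        entries[anticodon] = entries.get(anticodon, 0) + _parse_copy_number(
            row[1], f"{path}: row {i + 1}"
        )
    return TRNATable(entries=entries)


def _looks_numeric(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


def read_expression_table(path: str | Path) -> ExpressionTable:
    """Load a two-column (gene_id, abundance) table; duplicate ids are an error."""
    values: dict[str, float] = {}
    rows = _data_lines(path)
    for i, row in enumerate(rows):
        if len(row) < 2:
            raise ValidationError(f"{path}: row {i + 1} has fewer than 2 columns")
        if i == 0 and not _looks_numeric(row[1]):
            continue
        gene_id, text = row[0], row[1]
        try:
            abundance = float(text)
        except ValueError:
            raise ValidationError(f"{path}: row {i + 1}: abundance {text!r} not numeric")
        if abundance < 0:
            raise ValidationError(f"{path}: row {i + 1}: negative abundance for {gene_id!r}")
        if gene_id in values:
            raise ValidationError(f"{path}: duplicate gene id {gene_id!r}")
        values[gene_id] = abundance
    return ExpressionTable(values=values)


def read_cluster_table(path: str | Path) -> ClusterTable:
    """Load one cluster per row: cluster_id followed by member gene_ids."""
    clusters: dict[str, list[str]] = {}
    for i, row in enumerate(_data_lines(path)):
        cid = row[0]
        members = [g for f in row[1:] for g in f.split() if g]
        if cid in clusters:
            raise ValidationError(f"{path}: duplicate cluster id {cid!r}")
        if not members:
            raise ValidationError(f"{path}: row {i + 1}: cluster {cid!r} is empty")
        clusters[cid] = members
    return ClusterTable(clusters=clusters)


def read_id_list(path: str | Path) -> set[str]:
    """One id per line; blank lines ignored; duplicates collapse to a set."""
    ids = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            token = line.strip()
            if token:
                ids.add(token)
    return ids


def mark_excluded(records: Iterable[GeneRecord], exclude: set[str]) -> int:
    """Set is_excluded on records whose gene_id is in the exclusion set."""
    n = 0
    for rec in records:
        if rec.gene_id in exclude:
            rec.is_excluded = True
            n += 1
    return n


def write_table(rows, path: str | Path) -> None:
    """Write uniform records (dataclasses, dicts, or a DataFrame) as TSV.

    Floats carry >= 6 significant digits so numeric tables round-trip
    through read_table within 1e-6.
    """
    if isinstance(rows, pd.DataFrame):
        frame = rows
    else:
        rows = list(rows)
        if rows and is_dataclass(rows[0]):
            names = [f.name for f in dc_fields(rows[0])]
            frame = pd.DataFrame([asdict(r) for r in rows], columns=names)
        else:
            frame = pd.DataFrame(rows)
        if rows and isinstance(rows[0], dict):
            keys = set(rows[0])
            for r in rows:
                if set(r) != keys:
                    raise ValidationError("rows do not share field names")
    frame.to_csv(path, sep="\t", index=False, float_format="%.9g", lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by write_table."""
    return pd.read_csv(path, sep="\t")
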