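"""Readers and writers for the on-disk formats the pipeline touches.

Coordinate convention: everything in memory is 0-based half-open.
Conversion to/from the 1-based inclusive convention of GFF3 and GenBank
happens only at the file boundary, so no other module ever adjusts
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}
DNA_ALPHABET = set("ACGTN")

_GFF3_COLUMNS = (
    "seqid source type start end score strand phase attributes".split()
)


class FormatError(ValueError):
    """Malformed input file (bad alphabet, coordinates or table layout)."""


@dataclass
class SequenceRecord:
    """A protein or DNA sequence with its FASTA identity.

    ``id`` is the first whitespace-delimited token of the header;
    the remainder of the header is kept in ``description``.
    """

    id: str
    residues: str
    molecule: str = "protein"  # "protein" | "dna"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"record {self.id!r} has zero residues")
        self.residues = self.residues.upper()
        alphabet = PROTEIN_ALPHABET if self.molecule == "protein" else DNA_ALPHABET
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in alphabet:
                raise FormatError(
                    f"illegal character {ch!r} at position {pos} in record "
                    f"{self.id!r} ({self.molecule})"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class FeatureRecord:
    """A located feature (gene, domain, ...) in 0-based half-open coordinates."""

    seq_id: str
    start: int
    end: int
    strand: str
    feature_type: str
    attributes: dict = field(default_factory=dict)
    source: str = "."
    score: str = "."
    phase: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise FormatError(f"feature start {self.start} < 0")
        if self.end <= self.start:
            raise FormatError(
                f"feature end {self.end} not greater than start {self.start}"
            )


def read_fasta(path, molecule: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Residues are uppercased; ``*`` stop characters are stripped from
    protein records; wrapped lines are concatenated. Raises
    :class:`FormatError` on an empty file, an empty record, or an
    out-of-alphabet character (named with id and 1-based position).
    """
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if molecule == "protein":
            seq = seq.replace("*", "")
        if not rec.id:
            raise FormatError(f"record with empty id in {path}")
        if not seq:
            raise FormatError(f"record {rec.id!r} in {path} has zero residues")
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(
            SequenceRecord(id=rec.id, residues=seq, molecule=molecule,
                           description=desc)
        )
    if not records:
        raise FormatError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    """Write records as LF-terminated FASTA wrapped at ``width`` columns."""
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def read_gff3(path) -> list[FeatureRecord]:
    """Read GFF3 features, converting to 0-based half-open coordinates.

    Disk coordinates (1-based inclusive start s, end e) become internal
    (s-1, e). Comment and directive lines are skipped. Column 9 is parsed
    into a key->value attribute map.
    """
    features: list[FeatureRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            seqid, source, ftype, start_s, end_s, score, strand, phase, attrs = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            if end < start:
                raise FormatError(
                    f"{path}:{lineno}: end {end} < start {start}"
                )
            attributes = {}
            for pair in attrs.split(";"):
                pair = pair.strip()
                if pair and "=" in pair:
                    key, _, value = pair.partition("=")
                    attributes[key] = value
            features.append(
                FeatureRecord(
                    seq_id=seqid, start=start - 1, end=end, strand=strand,
                    feature_type=ftype, attributes=attributes,
                    source=source, score=score, phase=phase,
                )
            )
    return features


def write_gff3(features: Iterable[FeatureRecord], path) -> None:
    """Write features back to disk in 1-based inclusive GFF3 coordinates."""
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            fh.write(
                "\t".join(
                    [f.seq_id, f.source, f.feature_type, str(f.start + 1),
                     str(f.end), f.score, f.strand, f.phase, attrs]
                ) + "\n"
            )


def read_annotation_table(path) -> pd.DataFrame:
    """Read a per-gene annotation TSV.

    Mandatory columns: ``gene_id``, ``product``. Optional columns
    (``category``, ``cluster_id``) are added as nulls when absent.
    Duplicate gene ids are an error.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "product"):
        if col not in table.columns:
            raise FormatError(f"missing column {col}")
    dupes = table.loc[table["gene_id"].duplicated(), "gene_id"]
    if not dupes.empty:
        raise FormatError(f"duplicated gene_id {dupes.iloc[0]!r}")
    for col in ("category", "cluster_id"):
        if col not in table.columns:
            table[col] = pd.NA
    return table


def read_genbank_cds(path) -> list[SequenceRecord]:
    """Extract CDS translations from a GenBank file (read-only support)."""
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            translation = feat.qualifiers.get("translation", [None])[0]
            if translation is None:
                continue
            gene_id = feat.qualifiers.get(
                "locus_tag", feat.qualifiers.get("protein_id", ["unknown"])
            )[0]
            records.append(
                SequenceRecord(id=gene_id, residues=translation,
                               molecule="protein")
            )
    return records
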