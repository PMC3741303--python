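"""Readers and writers for every external representation the toolkit touches.

Annotated transcripts come in either as GenBank flat files or as a FASTA plus
a tab-separated CDS-coordinate table.  AltORF database tables are read/written
as TSV and read from the supplementary-spreadsheet dialect (XLSX, first tab =
AltORFs, optional second tab = conservation results).  Protein sets are FASTA.

Coordinate convention: everything at the I/O boundary is 1-based inclusive.
Internally the scanner uses 0-based half-open intervals; conversion happens
only here and in :mod:`altorf.core`.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.SeqFeature import CompoundLocation

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")

#: Missing-value token used in all TSV output.
NA = "."


class FormatError(ValueError):
    """A file does not follow the documented dialect."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and map U->T so a single alphabet {A,C,G,T,N} is used."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class TranscriptRecord:
    """One mature mRNA with its annotated reference ORF (CDS).

    ``cds_start``/``cds_end`` are 1-based inclusive positions of the first
    base of the start codon and the last base of the stop codon.
    """

    accession: str
    gene_symbol: str
    sequence: str
    cds_start: int
    cds_end: int
    version: Optional[str] = None

    def __post_init__(self) -> None:
        seq = normalize_sequence(self.sequence)
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"{self.accession}: sequence contains invalid characters {sorted(bad)}"
            )
        if not (1 <= self.cds_start < self.cds_end <= len(seq)):
            raise ValueError(
                f"{self.accession}: CDS {self.cds_start}..{self.cds_end} outside "
                f"sequence of length {len(seq)}"
            )
        if (self.cds_end - self.cds_start + 1) % 3 != 0:
            raise ValueError(
                f"{self.accession}: partial CDS — length "
                f"{self.cds_end - self.cds_start + 1} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start + 1

    @property
    def ref_protein_length(self) -> int:
        """Reference protein length in aa, stop codon excluded."""
        return self.cds_length // 3 - 1


@dataclass(frozen=True)
class AltOrfTableRow:
    """One AltORF table row; all coordinates 1-based on the mRNA."""

    gene_symbol: str
    transcript_accession: str
    ref_frame: str
    ref_start: int
    ref_stop: int
    alt_frame: str
    alt_start: int
    alt_stop: int
    alt_protein_sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "alt_protein_sequence", self.alt_protein_sequence.upper()
        )


ALTORF_TABLE_COLUMNS = (
    "gene_symbol",
    "transcript_accession",
    "ref_frame",
    "ref_start",
    "ref_stop",
    "alt_frame",
    "alt_start",
    "alt_stop",
    "alt_protein_sequence",
)

# The supplementary spreadsheets do not print their exact headers in the
# paper's text, so each canonical column carries a configurable alias list,
# matched case-insensitively after stripping whitespace/punctuation.
DEFAULT_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "gene_symbol": ("gene_symbol", "gene", "gene name", "gene_name", "symbol"),
    "transcript_accession": (
        "transcript_accession",
        "accession",
        "mrna accession",
        "accession number",
        "mrna",
        "transcript",
        "acc",
    ),
    "ref_frame": ("ref_frame", "reforf frame", "reference frame", "ref reading frame"),
    "ref_start": ("ref_start", "reforf start", "cds start", "ref start codon"),
    "ref_stop": ("ref_stop", "reforf stop", "cds stop", "cds end", "ref stop codon"),
    "alt_frame": ("alt_frame", "altorf frame", "frame", "alt reading frame"),
    "alt_start": ("alt_start", "altorf start", "start", "alt start codon"),
    "alt_stop": ("alt_stop", "altorf stop", "stop", "alt stop codon"),
    "alt_protein_sequence": (
        "alt_protein_sequence",
        "protein sequence",
        "predicted protein",
        "amino acid sequence",
        "aa sequence",
        "alternative protein sequence",
        "protein",
    ),
}

CONSERVATION_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "query_id": ("query_id", "query", "query accession", "accession", "accession number"),
    "subject_id": (
        "subject_id",
        "subject",
        "subject accession",
        "human accession",
        "human homolog",
        "homolog accession",
    ),
    "percent_identity": (
        "percent_identity",
        "% identity",
        "identity",
        "pident",
        "percent identity",
        "identity (%)",
    ),
    "e_value": ("e_value", "evalue", "e value", "expect"),
    "bit_score": ("bit_score", "bitscore", "bit score", "score"),
    "percent_similarity": (
        "percent_similarity",
        "% similarity",
        "similarity",
        "similarity (%)",
        "percent similarity",
    ),
}


def _canon(name: str) -> str:
    return "".join(ch for ch in str(name).lower() if ch.isalnum())


def _resolve_columns(
    header: Sequence[str],
    aliases: dict[str, tuple[str, ...]],
    required: Iterable[str],
) -> dict[str, int]:
    lookup = {_canon(h): i for i, h in enumerate(header)}
    resolved: dict[str, int] = {}
    for canonical, names in aliases.items():
        for alias in names:
            idx = lookup.get(_canon(alias))
            if idx is not None:
                resolved[canonical] = idx
                break
    missing = [c for c in required if c not in resolved]
    if missing:
        raise FormatError(
            f"missing mandatory column(s) {missing}; header was {list(header)}"
        )
    return resolved


# ---------------------------------------------------------------------------
# Transcript input
# ---------------------------------------------------------------------------

def read_genbank_transcripts(
    path: str | Path, skip_log: Optional[list[tuple[str, str]]] = None
) -> list[TranscriptRecord]:
    """Read mRNA records with a single unambiguous CDS from a GenBank flat file.

    Records with zero CDS features, more than one CDS feature, a joined or
    partial (``<``/``>``) CDS location, or a CDS length not divisible by 3
    are skipped; each skip is logged with a reason (and appended to
    ``skip_log`` when a list is supplied).

    Returns an empty list (with a warning) when no record is usable.
    """
    records: list[TranscriptRecord] = []

    def skip(acc: str, reason: str) -> None:
        logger.info("skipping %s: %s", acc, reason)
        if skip_log is not None:
            skip_log.append((acc, reason))

    for rec in SeqIO.parse(str(path), "genbank"):
        acc = rec.name or rec.id
        cds_features = [f for f in rec.features if f.type == "CDS"]
        if not cds_features:
            skip(acc, "no CDS feature")
            continue
        if len(cds_features) > 1:
            skip(acc, f"{len(cds_features)} CDS features")
            continue
        feat = cds_features[0]
        loc = feat.location
        if loc is None:
            skip(acc, "CDS feature without location")
            continue
        if isinstance(loc, CompoundLocation):
            skip(acc, "joined CDS location")
            continue
        if "<" in str(loc) or ">" in str(loc):
            skip(acc, "partial CDS (fuzzy boundary)")
            continue
        cds_start = int(loc.start) + 1  # Biopython is 0-based half-open
        cds_end = int(loc.end)
        gene = feat.qualifiers.get("gene", [rec.name])[0]
        version = rec.id if "." in rec.id else None
        try:
            records.append(
                TranscriptRecord(
                    accession=acc,
                    version=version,
                    gene_symbol=gene,
                    sequence=str(rec.seq),
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
        except ValueError as exc:
            skip(acc, str(exc))
    if not records:
        logger.warning("no usable mRNA records found in %s", path)
    return records


def read_fasta_with_cds_table(
    fasta: str | Path,
    cds_table: str | Path,
    skip_log: Optional[list[tuple[str, str]]] = None,
) -> list[TranscriptRecord]:
    """Join a transcript FASTA with a TSV of CDS coordinates by accession.

    The table needs columns ``accession``, ``gene_symbol``, ``cds_start``,
    ``cds_end`` (1-based inclusive).  Unmatched accessions on either side
    and rows failing the TranscriptRecord invariants are logged and skipped.
    """
    def skip(acc: str, reason: str) -> None:
        logger.info("skipping %s: %s", acc, reason)
        if skip_log is not None:
            skip_log.append((acc, reason))

    sequences = {rec.id.split()[0]: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}

    rows: dict[str, tuple[str, int, int]] = {}
    with open(cds_table, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise FormatError(f"{cds_table}: empty CDS table")
        needed = ("accession", "gene_symbol", "cds_start", "cds_end")
        idx = {}
        for col in needed:
            if col not in header:
                raise FormatError(f"{cds_table}: missing column '{col}'")
            idx[col] = header.index(col)
        for line in reader:
            if not line:
                continue
            rows[line[idx["accession"]]] = (
                line[idx["gene_symbol"]],
                int(line[idx["cds_start"]]),
                int(line[idx["cds_end"]]),
            )

    records = []
    for acc, seq in sequences.items():
        if acc not in rows:
            skip(acc, "no CDS table entry")
            continue
        gene, cds_start, cds_end = rows.pop(acc)
        try:
            records.append(
                TranscriptRecord(
                    accession=acc,
                    gene_symbol=gene,
                    sequence=seq,
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
        except ValueError as exc:
            skip(acc, f"coordinate error: {exc}")
    for acc in rows:
        skip(acc, "no FASTA sequence")
    return records


# ---------------------------------------------------------------------------
# AltORF tables
# ---------------------------------------------------------------------------

def write_altorf_table(rows: Iterable[AltOrfTableRow], path: str | Path) -> None:
    """Write AltORF rows as UTF-8 TSV with the fixed documented header."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ALTORF_TABLE_COLUMNS)
        for row in rows:
            writer.writerow(
                [
                    row.gene_symbol,
                    row.transcript_accession,
                    row.ref_frame,
                    row.ref_start,
                    row.ref_stop,
                    row.alt_frame,
                    row.alt_start,
                    row.alt_stop,
                    row.alt_protein_sequence,
                ]
            )


def read_altorf_database(
    path: str | Path,
    dialect: str = "tsv",
    column_aliases: Optional[dict[str, tuple[str, ...]]] = None,
) -> list[AltOrfTableRow]:
    """Read an AltORF database table.

    ``dialect="tsv"`` expects the header written by :func:`write_altorf_table`.
    ``dialect="supplementary_xlsx"`` reads the first worksheet of a
    supplementary-database spreadsheet, resolving columns case-insensitively
    through the alias table (override with ``column_aliases``).
    """
    aliases = column_aliases or DEFAULT_COLUMN_ALIASES
    required = list(ALTORF_TABLE_COLUMNS)

    if dialect == "tsv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader, None)
            if header is None:
                raise FormatError(f"{path}: empty table")
            resolved = _resolve_columns(header, aliases, required)
            raw_rows = list(reader)
    elif dialect == "supplementary_xlsx":
        import pandas as pd

        frame = pd.read_excel(path, sheet_name=0, dtype=object)
        header = [str(c) for c in frame.columns]
        resolved = _resolve_columns(header, aliases, required)
        raw_rows = frame.astype(object).values.tolist()
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    rows: list[AltOrfTableRow] = []
    for raw in raw_rows:
        if not raw or all(v in (None, "", NA) for v in raw):
            continue
        rows.append(
            AltOrfTableRow(
                gene_symbol=str(raw[resolved["gene_symbol"]]),
                transcript_accession=str(raw[resolved["transcript_accession"]]),
                ref_frame=str(raw[resolved["ref_frame"]]),
                ref_start=int(raw[resolved["ref_start"]]),
                ref_stop=int(raw[resolved["ref_stop"]]),
                alt_frame=str(raw[resolved["alt_frame"]]),
                alt_start=int(raw[resolved["alt_start"]]),
                alt_stop=int(raw[resolved["alt_stop"]]),
                alt_protein_sequence=str(raw[resolved["alt_protein_sequence"]]),
            )
        )
    logger.info("read %d AltORF rows from %s", len(rows), path)
    return rows


def read_conservation_table(
    path: str | Path,
    sheet: int = 1,
    column_aliases: Optional[dict[str, tuple[str, ...]]] = None,
):
    """Read the conservation tab of a supplementary database spreadsheet.

    Returns a pandas DataFrame with canonical column names (``query_id``,
    ``subject_id``, ``percent_identity``, plus ``e_value``/``bit_score``/
    ``percent_similarity`` when present).
    """
    import pandas as pd

    aliases = column_aliases or CONSERVATION_COLUMN_ALIASES
    frame = pd.read_excel(path, sheet_name=sheet, dtype=object)
    header = [str(c) for c in frame.columns]
    resolved = _resolve_columns(header, aliases, required=("query_id", "percent_identity"))
    out = pd.DataFrame(
        {canonical: frame.iloc[:, idx] for canonical, idx in resolved.items()}
    )
    out = out.dropna(subset=["query_id", "percent_identity"])
    out["percent_identity"] = out["percent_identity"].astype(float)
    return out


# ---------------------------------------------------------------------------
# Protein FASTA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinFastaEntry:
    """A protein FASTA entry; the header carries accession|kind|gene|source."""

    accession: str
    kind: str
    sequence: str
    gene_symbol: str = NA
    source_transcript: str = NA

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())


def write_protein_fasta(entries: Iterable[ProteinFastaEntry], path: str | Path) -> None:
    """Write protein entries; duplicate accessions are an error."""
    entries = list(entries)
    seen: dict[str, int] = {}
    for e in entries:
        seen[e.accession] = seen.get(e.accession, 0) + 1
    dupes = sorted(a for a, n in seen.items() if n > 1)
    if dupes:
        raise ValueError(f"duplicate identifiers on write: {dupes}")
    with open(path, "w", encoding="utf-8") as fh:
        for e in entries:
            fh.write(f">{e.accession}|{e.kind}|{e.gene_symbol}|{e.source_transcript}\n")
            seq = e.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_protein_fasta(path: str | Path) -> list[ProteinFastaEntry]:
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 4:
            raise FormatError(
                f"{path}: header {rec.id!r} is not 'accession|kind|gene|source-transcript'"
            )
        entries.append(
            ProteinFastaEntry(
                accession=parts[0],
                kind=parts[1],
                gene_symbol=parts[2],
                source_transcript=parts[3],
                sequence=str(rec.seq),
            )
        )
    return entries
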