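"""AltORF enumeration, frame/location classification, translation, dedup.

An AltORF is the region between an AUG and the nearest downstream in-frame
stop codon, distinct from the annotated reference ORF.  Scanning covers the
three absolute reading frames of the sense strand only; within each
stop-delimited slot the 5'-most AUG defines at most one candidate (first-AUG
rule).  Candidates are kept regardless of Kozak context or location, subject
to a minimum protein length (default 40 aa, stop excluded), the existence of
an in-frame stop on the transcript, and reference-ORF exclusion rules.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq

from altorf.transcript_io import TranscriptRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

#: Location classes relative to the annotated CDS (both intervals include
#: their stop codons).  ``spanning`` covers ORFs enclosing the whole CDS.
LOCATION_CLASSES = ("utr5", "utr5_cds", "cds", "cds_utr3", "utr3", "spanning")

FRAME_LABELS = ("+1", "+2", "+3")


@dataclass(frozen=True)
class AltOrf:
    """One predicted alternative ORF; coordinates 1-based inclusive."""

    transcript_accession: str
    start: int
    end: int
    frame_label: str
    location_class: str
    protein_sequence: str

    @property
    def length_aa(self) -> int:
        return (self.end - self.start + 1) // 3 - 1

    def key(self) -> tuple[str, int, int, str, str, str]:
        """Hashable identity tuple used for set comparisons."""
        return (
            self.transcript_accession,
            self.start,
            self.end,
            self.frame_label,
            self.location_class,
            self.protein_sequence,
        )


@dataclass(frozen=True)
class DistinctAltProtein:
    """A unique alternative protein sequence and the AltORF instances encoding it."""

    alt_accession: str
    protein_sequence: str
    instances: tuple[tuple[str, int, int], ...]

    @property
    def n_transcripts(self) -> int:
        return len({acc for acc, _, _ in self.instances})


def translate_orf(nt: str) -> str:
    """Translate an ORF with the standard genetic code.

    The terminal stop codon, if present, is dropped; any codon containing N
    yields 'X'.
    """
    if len(nt) % 3 != 0:
        raise ValueError(f"ORF length {len(nt)} not divisible by 3")
    protein = str(Seq(nt).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    return protein


def assign_frame(alt_start: int, cds_start: int) -> str:
    """Reading-frame label of an AltORF start relative to the RefORF start.

    +1 is the RefORF's own frame; +2 and +3 are the shifted frames.
    """
    return FRAME_LABELS[(alt_start - cds_start) % 3]


def classify_location(
    alt: tuple[int, int], cds: tuple[int, int]
) -> str:
    """Classify an AltORF interval against the CDS interval (1-based inclusive).

    Both intervals include their stop codons.  The RefORF interval itself must
    never reach this function.
    """
    a_start, a_end = alt
    c_start, c_end = cds
    if (a_start, a_end) == (c_start, c_end):
        raise RuntimeError("classify_location called on the RefORF interval itself")
    if a_end < c_start:
        return "utr5"
    if a_start > c_end:
        return "utr3"
    if c_start <= a_start and a_end <= c_end:
        return "cds"
    if a_start < c_start and a_end > c_end:
        return "spanning"
    if a_start < c_start:  # implies c_start <= a_end <= c_end
        return "utr5_cds"
    return "cds_utr3"  # implies c_start <= a_start <= c_end < a_end


def scan_altorfs(record: TranscriptRecord, min_len: int = 40) -> list[AltOrf]:
    """Enumerate AltORFs on a transcript.

    For each of the three absolute sense-strand frames, the sequence is
    partitioned into stop-delimited slots; within each slot the 5'-most AUG
    defines at most one candidate running to the slot's stop codon.  A
    candidate is kept iff an in-frame stop exists within the transcript, its
    protein is at least ``min_len`` aa (stop excluded), it is not the RefORF,
    and — in the RefORF's own frame — it does not share the RefORF's stop
    codon position (N-terminal truncations are not AltORFs).

    Output is sorted by (start, frame_label).  The minus strand is not
    scanned: mRNAs are already oriented.
    """
    if min_len < 0:
        raise ValueError("min_len must be non-negative")
    seq = record.sequence
    n = len(seq)
    out: list[AltOrf] = []
    for offset in range(3):
        open_start: int | None = None  # 0-based index of first ATG in current slot
        for i in range(offset, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if open_start is not None:
                    orf = _make_altorf(record, open_start, i + 3, min_len)
                    if orf is not None:
                        out.append(orf)
                    open_start = None
            elif codon == START_CODON and open_start is None:
                open_start = i
        # an open AUG with no downstream in-frame stop is discarded
    out.sort(key=lambda o: (o.start, o.frame_label))
    return out


def _make_altorf(
    record: TranscriptRecord, start0: int, end0: int, min_len: int
) -> AltOrf | None:
    """Build an AltOrf from 0-based half-open coordinates, applying filters."""
    start1, end1 = start0 + 1, end0
    length_aa = (end0 - start0) // 3 - 1
    if length_aa < min_len:
        return None
    if (start1, end1) == (record.cds_start, record.cds_end):
        return None
    frame = assign_frame(start1, record.cds_start)
    if frame == "+1" and end1 == record.cds_end:
        return None  # shares the RefORF stop codon: same-frame truncation
    location = classify_location((start1, end1), (record.cds_start, record.cds_end))
    protein = translate_orf(record.sequence[start0:end0])
    return AltOrf(
        transcript_accession=record.accession,
        start=start1,
        end=end1,
        frame_label=frame,
        location_class=location,
        protein_sequence=protein,
    )


def alt_accession_for(sequence: str) -> str:
    """Deterministic accession for a protein sequence: ALT_ + 12 hex digest chars."""
    digest = hashlib.sha256(sequence.encode("ascii")).hexdigest()
    return f"ALT_{digest[:12]}"


def dedupe_distinct(altorfs: Iterable[AltOrf]) -> list[DistinctAltProtein]:
    """Collapse AltORF instances to distinct alternative proteins.

    Grouping is exact protein-sequence equality; instance lists are sorted;
    output is sorted by accession for determinism.
    """
    groups: dict[str, set[tuple[str, int, int]]] = {}
    for orf in altorfs:
        groups.setdefault(orf.protein_sequence, set()).add(
            (orf.transcript_accession, orf.start, orf.end)
        )
    result = [
        DistinctAltProtein(
            alt_accession=alt_accession_for(seq),
            protein_sequence=seq,
            instances=tuple(sorted(instances)),
        )
        for seq, instances in groups.items()
    ]
    result.sort(key=lambda p: p.alt_accession)
    return result


def dedupe_sequences(sequences: Iterable[str]) -> int:
    """Number of distinct protein sequences (exact equality, case-folded)."""
    return len({s.upper() for s in sequences})


def scan_transcriptome(
    records: Sequence[TranscriptRecord], min_len: int = 40
) -> list[AltOrf]:
    """Scan many transcripts; concatenation of per-record scans."""
    out: list[AltOrf] = []
    for rec in records:
        out.extend(scan_altorfs(rec, min_len=min_len))
    return out
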