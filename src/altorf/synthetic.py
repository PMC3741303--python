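"""Seeded synthetic data: transcripts with planted AltORFs, peptide tables
with planted detections, and an independent brute-force scanning oracle.

The transcript generator draws a uniform background over {A,C,G,T}, splices
in planted ORFs built from an A-free interior codon alphabet (so they can
never create spurious AUGs or in-frame stops), then destroys every unintended
AUG trigram with minimal single-base edits to 'C' (lowest position first —
'C' cannot participate in an AUG, so the pass converges and never creates new
starts).  The annotated CDS of generated records is coordinate-only: the
scanner consumes annotation, not start-codon presence, which keeps every
(location class x frame) combination plantable, including same-frame ORFs
spanning or inside the CDS.

``brute_force_scan`` shares no code with :func:`altorf.core.scan_altorfs`;
it enumerates every AUG, walks codons to the nearest in-frame stop, keeps the
5'-most AUG per (frame, stop) pair, and applies the filters independently —
including its own codon table.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from altorf.core import AltOrf
from altorf.proteomics import PeptideObservation, ProteinDbEntry, digest_tryptic
from altorf.transcript_io import TranscriptRecord

_FRAME_RESIDUE = {"+1": 0, "+2": 1, "+3": 2}

# interior codons: all 27 codons over {C,G,T} — A-free, hence never a stop
# and never part of an AUG across any junction
_SAFE_CODONS = [a + b + c for a in "CGT" for b in "CGT" for c in "CGT"]

_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class PlantSpec:
    """A request to plant ``count`` AltORFs of one class/frame/length."""

    location_class: str
    frame_label: str
    length_aa: int
    count: int = 1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.frame_label not in _FRAME_RESIDUE:
            raise ValueError(f"unknown frame label {self.frame_label!r}")
        if self.length_aa < 1:
            raise ValueError("length_aa must be >= 1")
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.count > 1 and self.location_class in ("utr5_cds", "cds_utr3", "spanning"):
            raise ValueError(
                f"count > 1 unsupported for boundary class {self.location_class!r}"
            )


class InfeasiblePlantError(ValueError):
    """The requested plants do not fit the transcript geometry."""


def _safe_orf_nt(length_aa: int, rng: random.Random) -> str:
    """ATG + length_aa A-free codons + TAA stop; no internal AUG or in-frame stop."""
    interior = "".join(rng.choice(_SAFE_CODONS) for _ in range(length_aa - 1))
    return "ATG" + interior + "TAA"


def _aligned_start(lower: int, cds_start: int, residue: int) -> int:
    """Smallest 1-based position >= lower with (pos - cds_start) % 3 == residue."""
    shift = (residue - (lower - cds_start)) % 3
    return lower + shift


def generate_transcript(
    spec: PlantSpec,
    background_len: int = 600,
    seed: Optional[int] = None,
) -> tuple[TranscriptRecord, list[AltOrf]]:
    """Generate a transcript carrying exactly the planted AltORFs.

    Returns the record and the ground-truth AltOrf list (sorted by start).
    The same seed always yields byte-identical output.  Raises
    :class:`InfeasiblePlantError` naming the violated constraint when the
    geometry does not fit.
    """
    from altorf.core import classify_location, translate_orf

    rng = random.Random(seed if seed is not None else spec.seed)
    r = _FRAME_RESIDUE[spec.frame_label]
    orf_len = 3 * (spec.length_aa + 1)
    gap = 6

    # region sizing -------------------------------------------------------
    if spec.location_class == "spanning":
        cds_len = orf_len - 6 - ((orf_len - 6) % 3)
        if cds_len < 6:
            raise InfeasiblePlantError(
                "spanning plant needs length_aa >= 4 so the ORF can enclose a CDS"
            )
    elif spec.location_class == "cds":
        cds_len = orf_len + 9  # room for a frame-shifted start and a distinct stop
    else:
        cds_len = max(30, orf_len // 2 - (orf_len // 2) % 3)

    need = spec.count * (orf_len + gap) + gap
    utr5_len = need if spec.location_class in ("utr5", "utr5_cds", "spanning") else 30
    utr3_len = need if spec.location_class in ("utr3", "cds_utr3", "spanning") else 30
    total = utr5_len + cds_len + utr3_len
    if background_len > total:
        utr3_len += background_len - total
        total = background_len
    elif background_len < total:
        raise InfeasiblePlantError(
            f"background_len {background_len} too short: plants need {total} nt"
        )

    cds_start = utr5_len + 1
    cds_end = utr5_len + cds_len
    seq = rng.choices("ACGT", k=total)

    # plant placement -----------------------------------------------------
    plants: list[tuple[int, int]] = []  # 1-based inclusive intervals
    cls = spec.location_class
    for i in range(spec.count):
        if cls == "utr5":
            lower = (plants[-1][1] + gap + 1) if plants else 2
            start = _aligned_start(lower, cds_start, r)
            end = start + orf_len - 1
            if end >= cds_start:
                raise InfeasiblePlantError("utr5 plant does not fit upstream of the CDS")
        elif cls == "utr3":
            lower = (plants[-1][1] + gap + 1) if plants else cds_end + 2
            start = _aligned_start(lower, cds_start, r)
            end = start + orf_len - 1
            if end > total:
                raise InfeasiblePlantError("utr3 plant overruns the transcript end")
        elif cls == "cds":
            lower = (plants[-1][1] + gap + 1) if plants else cds_start + 1
            start = _aligned_start(max(lower, cds_start + 1), cds_start, r)
            end = start + orf_len - 1
            if spec.frame_label == "+1" and end == cds_end:
                start += 3
                end += 3
            if end >= cds_end:  # keep the +1 stop distinct from the RefORF stop
                raise InfeasiblePlantError("cds plant does not fit inside the CDS")
        elif cls == "utr5_cds":
            # end must land in [cds_start, cds_end]
            start = _aligned_start(2, cds_start, r)
            while start + orf_len - 1 < cds_start:
                start += 3
            end = start + orf_len - 1
            if not (start < cds_start <= end <= cds_end):
                raise InfeasiblePlantError("utr5_cds plant cannot straddle the 5' boundary")
            if spec.frame_label == "+1" and end == cds_end:
                raise InfeasiblePlantError("utr5_cds +1 plant would share the RefORF stop")
        elif cls == "cds_utr3":
            start = _aligned_start(cds_start, cds_start, r)
            while start + orf_len - 1 <= cds_end:
                start += 3
            end = start + orf_len - 1
            if not (start <= cds_end < end <= total):
                raise InfeasiblePlantError("cds_utr3 plant cannot straddle the 3' boundary")
        elif cls == "spanning":
            d1 = (-r) % 3 or 3
            start = cds_start - d1
            end = start + orf_len - 1
            if start < 1 or end <= cds_end or end > total:
                raise InfeasiblePlantError("spanning plant cannot enclose the CDS")
        else:
            raise InfeasiblePlantError(f"unknown location class {cls!r}")
        plants.append((start, end))
        orf_nt = _safe_orf_nt(spec.length_aa, rng)
        seq[start - 1 : end] = list(orf_nt)

    # destroy every AUG that is not a plant start -------------------------
    plant_starts = {s - 1 for s, _ in plants}
    in_plant = [False] * total
    for s, e in plants:
        for i in range(s - 1, e):
            in_plant[i] = True
    changed = True
    while changed:
        changed = False
        for i in range(total - 2):
            if seq[i] == "A" and seq[i + 1] == "T" and seq[i + 2] == "G":
                if i in plant_starts:
                    continue
                for j in (i, i + 1, i + 2):
                    if not in_plant[j]:
                        seq[j] = "C"
                        changed = True
                        break
                else:  # pragma: no cover - impossible with gapped plants
                    raise InfeasiblePlantError("unremovable AUG inside planted regions")

    record = TranscriptRecord(
        accession=f"SYN_{cls.upper()}_{spec.frame_label[1]}_{seed if seed is not None else spec.seed}",
        gene_symbol=f"SYNG_{cls}",
        sequence="".join(seq),
        cds_start=cds_start,
        cds_end=cds_end,
    )
    truth = []
    for start, end in sorted(plants):
        truth.append(
            AltOrf(
                transcript_accession=record.accession,
                start=start,
                end=end,
                frame_label=spec.frame_label,
                location_class=classify_location((start, end), (cds_start, cds_end)),
                protein_sequence=translate_orf(record.sequence[start - 1 : end]),
            )
        )
        if truth[-1].location_class != cls:
            raise InfeasiblePlantError(
                f"plant at {start}..{end} classifies as {truth[-1].location_class}, "
                f"wanted {cls}"
            )
    return record, truth


def random_transcript(
    seed: int, min_len: int = 100, max_len: int = 3000
) -> TranscriptRecord:
    """A uniform random transcript with a random valid CDS annotation."""
    rng = random.Random(seed)
    n = rng.randrange(min_len, max_len + 1)
    seq = "".join(rng.choices("ACGT", k=n))
    cds_start = rng.randrange(1, n - 5)
    max_codons = (n - cds_start + 1) // 3
    cds_len = 3 * rng.randrange(2, max_codons + 1)
    return TranscriptRecord(
        accession=f"RND_{seed}",
        gene_symbol=f"RG{seed % 97}",
        sequence=seq,
        cds_start=cds_start,
        cds_end=cds_start + cds_len - 1,
    )


# ---------------------------------------------------------------------------
# Independent oracle
# ---------------------------------------------------------------------------

_ORACLE_CODONS = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}


def brute_force_scan(record: TranscriptRecord, min_len: int = 40) -> list[AltOrf]:
    """Independent AltORF oracle (shares no code with the production scanner)."""
    seq = record.sequence
    n = len(seq)
    # every AUG with its nearest downstream in-frame stop
    candidates: dict[tuple[int, int], int] = {}  # (frame, stop_end0) -> min start0
    for i in range(n - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i + 3
        stop_end = None
        while j + 3 <= n:
            if seq[j : j + 3] in _STOPS:
                stop_end = j + 3
                break
            j += 3
        if stop_end is None:
            continue
        key = (i % 3, stop_end)
        if key not in candidates or i < candidates[key]:
            candidates[key] = i  # first-AUG rule per stop-delimited slot
    out = []
    for (_, stop_end), start0 in candidates.items():
        start1, end1 = start0 + 1, stop_end
        if (stop_end - start0) // 3 - 1 < min_len:
            continue
        if (start1, end1) == (record.cds_start, record.cds_end):
            continue
        rel = (start1 - record.cds_start) % 3
        if rel == 0 and end1 == record.cds_end:
            continue
        # independent location classification
        cs, ce = record.cds_start, record.cds_end
        if end1 < cs:
            cls = "utr5"
        elif start1 > ce:
            cls = "utr3"
        elif start1 >= cs and end1 <= ce:
            cls = "cds"
        elif start1 < cs and end1 > ce:
            cls = "spanning"
        elif start1 < cs:
            cls = "utr5_cds"
        else:
            cls = "cds_utr3"
        protein = []
        for k in range(start0, stop_end - 3, 3):
            protein.append(_ORACLE_CODONS.get(seq[k : k + 3], "X"))
        out.append(
            AltOrf(
                transcript_accession=record.accession,
                start=start1,
                end=end1,
                frame_label=("+1", "+2", "+3")[rel],
                location_class=cls,
                protein_sequence="".join(protein),
            )
        )
    out.sort(key=lambda o: (o.start, o.frame_label))
    return out


# ---------------------------------------------------------------------------
# Planted peptide observations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedDetection:
    """Plan entry for one protein in a synthetic peptide table."""

    protein_id: str
    n_peptides: int = 2
    pep: float = 0.01
    acetylated_nterm: bool = False
    intensity: float = 1e6
    sample_id: str = "s1"


def generate_peptide_table(
    db_entries: Sequence[ProteinDbEntry],
    plan: Sequence[PlantedDetection],
    seed: int = 0,
) -> tuple[list[PeptideObservation], dict[str, bool]]:
    """Emit tryptic peptide observations for planted proteins.

    Every emitted peptide is chosen to be unique to its protein within the
    forward database, so the truth map records survival of
    ``filter_identifications`` as simply ``pep < 0.05``.  Acetylation plants
    place an N-terminally acetylated peptide at protein position 1 (or 2
    behind an initiator Met).  Same seed, same table.
    """
    rng = random.Random(seed)
    forward = {e.id: e.sequence for e in db_entries if e.kind != "decoy"}
    observations: list[PeptideObservation] = []
    truth: dict[str, bool] = {}
    for item in plan:
        if item.protein_id not in forward:
            raise ValueError(f"plan references unknown protein {item.protein_id!r}")
        protein = forward[item.protein_id]
        peptides = digest_tryptic(protein, max_missed=2, min_len=7, max_len=40)
        others = [seq for pid, seq in forward.items() if pid != item.protein_id]
        unique = [p for p in peptides if not any(p.sequence in o for o in others)]
        if not unique:
            raise ValueError(
                f"protein {item.protein_id!r} has no peptide unique to it"
            )
        chosen = []
        if item.acetylated_nterm:
            nterm = [p for p in unique if p.start in (1, 2)]
            if not nterm:
                raise ValueError(
                    f"protein {item.protein_id!r} has no unique N-terminal peptide"
                )
            chosen.append((nterm[0], True))
        pool = [p for p in unique if all(p is not c for c, _ in chosen)]
        rng.shuffle(pool)
        for p in pool[: max(0, item.n_peptides - len(chosen))]:
            chosen.append((p, False))
        for pep, acetyl in chosen:
            observations.append(
                PeptideObservation(
                    sequence=pep.sequence,
                    is_nterm_acetylated=acetyl,
                    intensity=item.intensity * rng.uniform(0.5, 1.5),
                    sample_id=item.sample_id,
                    pep_score=item.pep,
                )
            )
        truth[item.protein_id] = item.pep < 0.05
    return observations, truth
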