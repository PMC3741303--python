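"""Augmented proteomics search space and peptide-evidence post-processing.

Builds the combined reference + alternative + contaminant search database
with one reversed decoy per forward entry, digests proteins in silico
(trypsin/P, missed cleavages), maps identified peptides back to proteins with
fully tryptic termini, groups indistinguishable proteins, and applies the
retention rules: posterior error probability strictly below threshold and at
least one unique peptide.  Spectral scoring itself is out of scope — PEP
values and intensities are consumed from upstream search-engine tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

from scipy.stats import hypergeom

DECOY_PREFIX = "REV_"


@dataclass(frozen=True)
class ProteinDbEntry:
    id: str
    kind: str  # reference | alternative | contaminant | decoy
    sequence: str
    source_id: Optional[str] = None  # forward entry id, decoys only

    def __post_init__(self) -> None:
        if self.kind not in ("reference", "alternative", "contaminant", "decoy"):
            raise ValueError(f"unknown entry kind {self.kind!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass
class PeptideObservation:
    """One identified peptide from an upstream search-engine table."""

    sequence: str
    is_nterm_acetylated: bool = False
    intensity: float = 0.0
    sample_id: str = "."
    pep_score: Optional[float] = None
    assigned_proteins: frozenset[str] = frozenset()
    is_unique: bool = False
    decoy_only: bool = False  # anomaly flag: matched nothing but decoys

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")
        if self.pep_score is not None and not (0.0 <= self.pep_score <= 1.0):
            raise ValueError("pep_score must lie in [0, 1]")


@dataclass
class DetectionSummary:
    protein_id: str
    n_peptides: int = 0
    n_unique_peptides: int = 0
    coverage_pct: float = 0.0
    tis_supported: bool = False
    samples: frozenset[str] = frozenset()
    pep_score: Optional[float] = None
    mean_intensity: float = 0.0


@dataclass(frozen=True)
class Peptide:
    """A digested fragment with 1-based inclusive coordinates on its protein."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int


def build_search_fasta(
    reference: Mapping[str, str],
    alternative: Mapping[str, str],
    contaminants: Mapping[str, str],
) -> list[ProteinDbEntry]:
    """Combine the three forward namespaces and append one reversed decoy each.

    Output size is exactly ``2 * (n_ref + n_alt + n_cont)``.  Identifier
    collisions across namespaces are an error.
    """
    namespaces = [
        ("reference", reference),
        ("alternative", alternative),
        ("contaminant", contaminants),
    ]
    seen: dict[str, str] = {}
    entries: list[ProteinDbEntry] = []
    for kind, proteins in namespaces:
        for pid, seq in proteins.items():
            if pid in seen:
                raise ValueError(
                    f"id collision: {pid!r} present in both {seen[pid]} and {kind}"
                )
            seen[pid] = kind
            entries.append(ProteinDbEntry(id=pid, kind=kind, sequence=seq))
    decoys = [
        ProteinDbEntry(
            id=DECOY_PREFIX + e.id,
            kind="decoy",
            sequence=e.sequence[::-1],
            source_id=e.id,
        )
        for e in entries
    ]
    return entries + decoys


def digest_tryptic(
    protein: str,
    max_missed: int = 2,
    min_len: int = 7,
    max_len: int = 40,
) -> list[Peptide]:
    """In-silico trypsin/P digestion.

    Cleaves after every K or R, including before proline; returns every
    contiguous union of fragments with at most ``max_missed`` internal
    cleavage sites, filtered to ``min_len <= length <= max_len``.
    """
    protein = protein.upper()
    n = len(protein)
    if n == 0:
        return []
    # 0-based half-open fragment boundaries
    cuts = [0] + [i + 1 for i in range(n - 1) if protein[i] in "KR"] + [n]
    peptides: list[Peptide] = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(cuts))):
            start, end = cuts[i], cuts[j]
            if min_len <= end - start <= max_len:
                peptides.append(
                    Peptide(
                        sequence=protein[start:end],
                        start=start + 1,
                        end=end,
                        missed_cleavages=j - i - 1,
                    )
                )
    return peptides


def _tryptic_match_positions(protein: str, peptide: str) -> list[int]:
    """1-based start positions where ``peptide`` occurs with tryptic termini.

    The N-terminus is valid at the protein start, after K/R, or at position 2
    when residue 1 is M (initiator-Met cleavage).  The C-terminal residue must
    be K/R or fall at the protein end (trypsin/P: proline does not block).
    """
    positions = []
    idx = protein.find(peptide)
    while idx != -1:
        start1 = idx + 1
        end1 = idx + len(peptide)
        nterm_ok = (
            start1 == 1
            or protein[idx - 1] in "KR"
            or (start1 == 2 and protein[0] == "M")
        )
        cterm_ok = peptide[-1] in "KR" or end1 == len(protein)
        if nterm_ok and cterm_ok:
            positions.append(start1)
        idx = protein.find(peptide, idx + 1)
    return positions


@dataclass
class MappingResult:
    observations: list[PeptideObservation]
    #: protein id -> group id (groups merge proteins with identical peptide sets)
    group_of: dict[str, str]
    #: group id -> sorted tuple of member protein ids
    groups: dict[str, tuple[str, ...]]
    #: (peptide sequence, protein id) -> 1-based match start positions
    positions: dict[tuple[str, str], tuple[int, ...]]


def map_peptides(
    observations: Iterable[PeptideObservation],
    db_entries: Sequence[ProteinDbEntry],
) -> MappingResult:
    """Assign peptides to forward database entries and group indistinguishables.

    Each peptide is assigned to every non-decoy entry containing it as an
    exact substring with tryptic termini.  Proteins whose assigned peptide
    sets are identical are merged into one group; a peptide is unique iff all
    its assigned proteins belong to a single group.  Peptides matching only
    decoy entries are flagged as anomalies and excluded from assignments.
    """
    forward = [e for e in db_entries if e.kind != "decoy"]
    decoys = [e for e in db_entries if e.kind == "decoy"]

    observations = [replace(o) for o in observations]
    positions: dict[tuple[str, str], tuple[int, ...]] = {}
    peptide_proteins: dict[str, set[str]] = {}
    for obs in observations:
        if obs.sequence in peptide_proteins:
            continue
        matches: set[str] = set()
        for entry in forward:
            pos = _tryptic_match_positions(entry.sequence, obs.sequence)
            if pos:
                matches.add(entry.id)
                positions[(obs.sequence, entry.id)] = tuple(pos)
        peptide_proteins[obs.sequence] = matches

    protein_peptides: dict[str, frozenset[str]] = {}
    for entry in forward:
        pepset = frozenset(
            seq for seq, prots in peptide_proteins.items() if entry.id in prots
        )
        if pepset:
            protein_peptides[entry.id] = pepset

    # group proteins with identical assigned-peptide sets
    by_pepset: dict[frozenset[str], list[str]] = {}
    for pid, pepset in protein_peptides.items():
        by_pepset.setdefault(pepset, []).append(pid)
    group_of: dict[str, str] = {}
    groups: dict[str, tuple[str, ...]] = {}
    for members in by_pepset.values():
        members = tuple(sorted(members))
        gid = members[0]
        groups[gid] = members
        for pid in members:
            group_of[pid] = gid

    for obs in observations:
        assigned = peptide_proteins[obs.sequence]
        if not assigned:
            decoy_hit = any(
                _tryptic_match_positions(d.sequence, obs.sequence) for d in decoys
            )
            obs.assigned_proteins = frozenset()
            obs.is_unique = False
            obs.decoy_only = decoy_hit
            continue
        obs.assigned_proteins = frozenset(assigned)
        obs.is_unique = len({group_of[p] for p in assigned}) == 1
        obs.decoy_only = False
    return MappingResult(
        observations=observations,
        group_of=group_of,
        groups=groups,
        positions=positions,
    )


def summarize_detections(
    mapping: MappingResult, db_entries: Sequence[ProteinDbEntry]
) -> list[DetectionSummary]:
    """Per-protein evidence rollup from mapped observations.

    For every forward protein with at least one assigned peptide: peptide and
    unique-peptide counts, sequence coverage, TIS support from N-terminally
    acetylated peptides, the sample set, the best (lowest) observation PEP,
    and the mean intensity.
    """
    sequences = {e.id: e.sequence for e in db_entries if e.kind != "decoy"}
    out = []
    for pid, seq in sequences.items():
        assigned = [o for o in mapping.observations if pid in o.assigned_proteins]
        if not assigned:
            continue
        peptides = []
        tis_pairs = []
        for obs in assigned:
            for start in mapping.positions.get((obs.sequence, pid), ()):
                peptides.append(
                    Peptide(
                        sequence=obs.sequence,
                        start=start,
                        end=start + len(obs.sequence) - 1,
                        missed_cleavages=0,
                    )
                )
                tis_pairs.append((obs, start))
        peps = [o.pep_score for o in assigned if o.pep_score is not None]
        out.append(
            DetectionSummary(
                protein_id=pid,
                n_peptides=len(assigned),
                n_unique_peptides=sum(1 for o in assigned if o.is_unique),
                coverage_pct=compute_coverage(seq, peptides),
                tis_supported=validate_tis(seq, tis_pairs),
                samples=frozenset(o.sample_id for o in assigned),
                pep_score=min(peps) if peps else None,
                mean_intensity=(
                    sum(o.intensity for o in assigned) / len(assigned)
                ),
            )
        )
    out.sort(key=lambda s: s.protein_id)
    return out


def filter_identifications(
    summaries: Iterable[DetectionSummary],
    pep_threshold: float = 0.05,
    min_unique: int = 1,
) -> list[DetectionSummary]:
    """Retain summaries with PEP strictly below threshold and enough unique peptides."""
    return [
        s
        for s in summaries
        if s.pep_score is not None
        and s.pep_score < pep_threshold
        and s.n_unique_peptides >= min_unique
    ]


def compute_coverage(protein: str, peptides: Iterable[Peptide]) -> float:
    """Percent of protein residues covered by at least one peptide."""
    n = len(protein)
    covered = [False] * n
    for pep in peptides:
        if pep.start < 1 or pep.end > n or pep.start > pep.end:
            raise ValueError(
                f"peptide coordinates {pep.start}..{pep.end} out of range 1..{n}"
            )
        for i in range(pep.start - 1, pep.end):
            covered[i] = True
    return 100.0 * sum(covered) / n if n else 0.0


def validate_tis(protein: str, observations: Iterable[tuple[PeptideObservation, int]]) -> bool:
    """True iff an N-terminally acetylated peptide sits at the protein N-terminus.

    ``observations`` pairs each observation with its 1-based start position on
    the protein.  Position 1 qualifies, as does position 2 when residue 1 is M
    (initiator-Met cleavage).
    """
    for obs, start in observations:
        if not obs.is_nterm_acetylated:
            continue
        if start == 1 or (start == 2 and protein[:1] == "M"):
            return True
    return False


@dataclass(frozen=True)
class CoexpressedGene:
    gene_symbol: str
    reference_mean_intensity: float
    alternative_mean_intensity: float


def coexpression_genes(
    detections: Iterable[DetectionSummary],
    gene_map: Mapping[str, str],
    kind_map: Mapping[str, str],
) -> list[CoexpressedGene]:
    """Genes where both a reference and an alternative protein were detected.

    ``detections`` should already have passed :func:`filter_identifications`.
    Per-gene mean intensities of each kind are reported.
    """
    per_gene: dict[str, dict[str, list[float]]] = {}
    for det in detections:
        gene = gene_map.get(det.protein_id)
        kind = kind_map.get(det.protein_id)
        if gene is None or kind not in ("reference", "alternative"):
            continue
        per_gene.setdefault(gene, {}).setdefault(kind, []).append(det.mean_intensity)
    out = []
    for gene in sorted(per_gene):
        kinds = per_gene[gene]
        if "reference" in kinds and "alternative" in kinds:
            out.append(
                CoexpressedGene(
                    gene_symbol=gene,
                    reference_mean_intensity=sum(kinds["reference"]) / len(kinds["reference"]),
                    alternative_mean_intensity=sum(kinds["alternative"]) / len(kinds["alternative"]),
                )
            )
    return out


def overlap_enrichment(n_a: int, n_b: int, k: int, universe: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k) of a set overlap.

    X counts the intersection of a fixed set of size ``n_a`` with a uniformly
    drawn set of size ``n_b`` from ``universe`` elements.  Computed in
    log-space by scipy's survival function, so extreme tails are exact to
    double precision.
    """
    if min(n_a, n_b, k, universe) < 0:
        raise ValueError("counts must be non-negative")
    if max(n_a, n_b) > universe:
        raise ValueError("set sizes exceed the universe")
    if k > min(n_a, n_b):
        raise ValueError("overlap exceeds the smaller set")
    if k < n_a + n_b - universe:
        raise ValueError("overlap below the forced minimum n_a + n_b - universe")
    return float(hypergeom.sf(k - 1, universe, n_a, n_b))
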