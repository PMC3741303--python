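"""Best-hit cross-species protein similarity profiling.

Each query is aligned locally (BLOSUM62, affine gaps 11/1) against every
subject; only the best-scoring hit is kept, and only when its expectation
value passes the cutoff (default 1e-4).  The expectation follows the
Karlin–Altschul form E = K * m * n * exp(-lambda * S) with the standard
gapped constants for BLOSUM62 11/1 (lambda = 0.267, K = 0.041); m is the raw
query length and n the total residue count of the subject database
(effective-length correction is deliberately omitted).  The aligner is
pluggable so an external search engine can substitute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional

from Bio.Align import PairwiseAligner, substitution_matrices

GAPPED_LAMBDA = 0.267
GAPPED_K = 0.041

#: alignment callable: (query, subject) -> (score, n_identities, n_columns)
AlignerFn = Callable[[str, str], tuple[float, int, int]]


@dataclass(frozen=True)
class ConservationHit:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_score: float
    e_value: float
    query_species: str = "."
    subject_species: str = "."


def _default_aligner() -> AlignerFn:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # BLAST convention: a gap of length L costs 11 + L, i.e. the first gap
    # residue costs 12 and each extension 1.
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1

    def align(query: str, subject: str) -> tuple[float, int, int]:
        alignments = aligner.align(query, subject)
        try:
            best = alignments[0]
        except IndexError:
            return 0.0, 0, 0
        counts = best.counts()
        columns = counts.identities + counts.mismatches + counts.gaps
        return float(best.score), int(counts.identities), int(columns)

    return align


def karlin_altschul_evalue(
    score: float, m: int, n: int, lam: float = GAPPED_LAMBDA, k: float = GAPPED_K
) -> float:
    """E = K * m * n * exp(-lambda * S), evaluated in log space."""
    if m <= 0 or n <= 0:
        raise ValueError("sequence lengths must be positive")
    log_e = math.log(k) + math.log(m) + math.log(n) - lam * score
    return math.exp(log_e)


def best_hit(
    query_id: str,
    query: str,
    subject_db: Mapping[str, str],
    e_cutoff: float = 1e-4,
    aligner: Optional[AlignerFn] = None,
    lam: float = GAPPED_LAMBDA,
    k: float = GAPPED_K,
    query_species: str = ".",
    subject_species: str = ".",
) -> Optional[ConservationHit]:
    """Best local-alignment hit of one query against a subject database.

    Returns None for an empty database or when the best hit's E-value exceeds
    the cutoff.  Ties on score break to the lowest subject id.
    """
    if not subject_db:
        return None
    db_residues = sum(len(s) for s in subject_db.values())
    align = aligner or _default_aligner()
    best: Optional[tuple[float, str, int, int]] = None
    for subject_id in sorted(subject_db):
        score, identities, columns = align(query, subject_db[subject_id])
        if columns == 0:
            continue
        if best is None or score > best[0]:
            best = (score, subject_id, identities, columns)
    if best is None:
        return None
    score, subject_id, identities, columns = best
    e_value = karlin_altschul_evalue(score, len(query), db_residues, lam, k)
    if e_value > e_cutoff:
        return None
    return ConservationHit(
        query_id=query_id,
        subject_id=subject_id,
        percent_identity=100.0 * identities / columns,
        alignment_score=score,
        e_value=e_value,
        query_species=query_species,
        subject_species=subject_species,
    )


@dataclass(frozen=True)
class ConservationProfile:
    """Aggregated best-hit identities: 1%-bin histogram, median, count."""

    histogram: Mapping[int, int]
    median_identity: float
    n_conserved: int

    @classmethod
    def from_identities(cls, identities: Iterable[float]) -> "ConservationProfile":
        values = sorted(identities)
        histogram: dict[int, int] = {}
        for v in values:
            b = min(100, int(math.floor(v)))
            histogram[b] = histogram.get(b, 0) + 1
        if not values:
            return cls(histogram={}, median_identity=float("nan"), n_conserved=0)
        mid = len(values) // 2
        if len(values) % 2:
            median = values[mid]
        else:
            median = (values[mid - 1] + values[mid]) / 2.0
        return cls(histogram=histogram, median_identity=median, n_conserved=len(values))


def conservation_profile(
    query_db: Mapping[str, str],
    subject_db: Mapping[str, str],
    e_cutoff: float = 1e-4,
    aligner: Optional[AlignerFn] = None,
) -> tuple[list[ConservationHit], ConservationProfile]:
    """Best hit per query, aggregated into an identity histogram and median."""
    hits = []
    align = aligner or _default_aligner()
    for query_id in sorted(query_db):
        hit = best_hit(
            query_id, query_db[query_id], subject_db, e_cutoff=e_cutoff, aligner=align
        )
        if hit is not None:
            hits.append(hit)
    profile = ConservationProfile.from_identities(h.percent_identity for h in hits)
    return hits, profile


HIT_TABLE_COLUMNS = (
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_score",
    "e_value",
)


def write_hit_table(hits: Iterable[ConservationHit], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(HIT_TABLE_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}\t"
                f"{h.alignment_score:.1f}\t{h.e_value:.3g}\n"
            )
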