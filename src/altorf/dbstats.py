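"""Database-level summary statistics for an AltORF prediction run.

Percentages over location classes are computed at the instance level (one
table row = one AltORF on one transcript); gene-level statistics collapse
transcripts by gene symbol.  Medians of integer inputs are integer-valued
(lower median for even counts).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from altorf.core import AltOrf, LOCATION_CLASSES
from altorf.transcript_io import TranscriptRecord


def low_median(values: Sequence[float]) -> float:
    """Lower median: element at index (n-1)//2 of the sorted values."""
    if not values:
        raise ValueError("median of empty sequence")
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


@dataclass(frozen=True)
class DbSummary:
    n_altorf_instances: int
    n_distinct_proteins: int
    n_transcripts_total: int
    n_transcripts_with_altorf: int
    fraction_with_altorf: float          # percent
    mean_altorfs_per_mrna: float
    median_alt_length_aa: float
    median_ref_length_aa: float
    location_percentages: Mapping[str, float]
    per_mrna_count_histogram: Mapping[int, int]
    genes_with_cds_contained_altorf: float  # percent of genes


def location_distribution(altorfs: Iterable[AltOrf]) -> dict[str, float]:
    """Percentage of AltORF instances per location class (sums to 100)."""
    counts = Counter(o.location_class for o in altorfs)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty-set: no AltORF instances to classify")
    return {cls: 100.0 * counts.get(cls, 0) / total for cls in LOCATION_CLASSES}


def summarize(
    altorfs: Sequence[AltOrf],
    transcripts: Sequence[TranscriptRecord],
    ref_proteins: Optional[Sequence[str]] = None,
) -> DbSummary:
    """Compute all database-level summary fields.

    ``transcripts`` must include mRNAs with zero AltORFs (they are the
    denominator of the per-mRNA statistics).  Reference protein lengths come
    from ``ref_proteins`` sequences when given, else from the annotated CDS
    lengths of the transcripts.
    """
    if not transcripts:
        raise ValueError("empty transcript set")

    per_transcript = Counter(o.transcript_accession for o in altorfs)
    n_total = len(transcripts)
    n_with = sum(1 for t in transcripts if per_transcript.get(t.accession, 0) > 0)
    histogram = Counter(per_transcript.get(t.accession, 0) for t in transcripts)

    distinct = {o.protein_sequence for o in altorfs}
    alt_lengths = [o.length_aa for o in altorfs]
    if ref_proteins is not None:
        ref_lengths = [len(p) for p in ref_proteins]
    else:
        ref_lengths = [t.ref_protein_length for t in transcripts]

    if altorfs:
        location_pct = location_distribution(altorfs)
        median_alt = low_median(alt_lengths)
    else:
        location_pct = {cls: 0.0 for cls in LOCATION_CLASSES}
        median_alt = 0

    # gene level: a gene counts when any of its transcripts carries a
    # CDS-contained AltORF
    gene_of = {t.accession: t.gene_symbol for t in transcripts}
    all_genes = set(gene_of.values())
    genes_cds = {
        gene_of[o.transcript_accession]
        for o in altorfs
        if o.location_class == "cds" and o.transcript_accession in gene_of
    }

    return DbSummary(
        n_altorf_instances=len(altorfs),
        n_distinct_proteins=len(distinct),
        n_transcripts_total=n_total,
        n_transcripts_with_altorf=n_with,
        fraction_with_altorf=100.0 * n_with / n_total,
        mean_altorfs_per_mrna=len(altorfs) / n_total,
        median_alt_length_aa=median_alt,
        median_ref_length_aa=low_median(ref_lengths) if ref_lengths else 0,
        location_percentages=location_pct,
        per_mrna_count_histogram=dict(sorted(histogram.items())),
        genes_with_cds_contained_altorf=100.0 * len(genes_cds) / len(all_genes),
    )


def summary_table(summary: DbSummary) -> list[tuple[str, str]]:
    """Flatten a DbSummary into (key, value) rows for TSV reporting."""
    rows: list[tuple[str, str]] = [
        ("n_altorf_instances", str(summary.n_altorf_instances)),
        ("n_distinct_proteins", str(summary.n_distinct_proteins)),
        ("n_transcripts_total", str(summary.n_transcripts_total)),
        ("n_transcripts_with_altorf", str(summary.n_transcripts_with_altorf)),
        ("fraction_with_altorf_pct", f"{summary.fraction_with_altorf:.2f}"),
        ("mean_altorfs_per_mrna", f"{summary.mean_altorfs_per_mrna:.2f}"),
        ("median_alt_length_aa", str(summary.median_alt_length_aa)),
        ("median_ref_length_aa", str(summary.median_ref_length_aa)),
        (
            "genes_with_cds_contained_altorf_pct",
            f"{summary.genes_with_cds_contained_altorf:.2f}",
        ),
    ]
    for cls, pct in summary.location_percentages.items():
        rows.append((f"location_pct_{cls}", f"{pct:.2f}"))
    for count, n in summary.per_mrna_count_histogram.items():
        rows.append((f"mrna_with_{count}_altorfs", str(n)))
    return rows
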