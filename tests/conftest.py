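import pytest

from altorf.transcript_io import TranscriptRecord


@pytest.fixture
def toy_a() -> TranscriptRecord:
    # CDS 1..9 is ATG AAA TGA; one downstream ORF at 10..18 (ATG GCC TAA)
    return TranscriptRecord(
        accession="TOYA", gene_symbol="toyA", sequence="ATGAAATGAATGGCCTAA",
        cds_start=1, cds_end=9,
    )


@pytest.fixture
def toy_b() -> TranscriptRecord:
    # CDS 1..15; +2 frame ORF at 5..19 encoding MQCE, crossing into the 3'UTR
    return TranscriptRecord(
        accession="TOYB", gene_symbol="toyB", sequence="ATGGATGCAGTGTGAATAGG",
        cds_start=1, cds_end=15,
    )


def genbank_record(accession: str, gene: str, seq: str, cds_start: int, cds_end: int,
                   cds_line: str | None = None, n_cds: int = 1) -> str:
    """Minimal GenBank flat-file record.

    ``cds_line`` overrides the location string (e.g. ``"<1..9"`` for a partial
    CDS); ``n_cds=0`` omits the CDS feature, ``n_cds=2`` duplicates it.
    """
    location = cds_line or f"{cds_start}..{cds_end}"
    lines = [
        f"LOCUS       {accession:<16} {len(seq):>11} bp    mRNA    linear   PRI 01-JAN-2012",
        f"DEFINITION  synthetic test record {accession}.",
        f"ACCESSION   {accession}",
        f"VERSION     {accession}.1",
        "FEATURES             Location/Qualifiers",
        f"     source          1..{len(seq)}",
        '                     /organism="Homo sapiens"',
    ]
    for _ in range(n_cds):
        lines.append(f"     CDS             {location}")
        lines.append(f'                     /gene="{gene}"')
    lines.append("ORIGIN")
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60]
        grouped = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {grouped.lower()}")
    lines.append("//")
    return "\n".join(lines) + "\n"


@pytest.fixture
def make_genbank(tmp_path):
    def _make(records: list[tuple], name="test.gb"):
        path = tmp_path / name
        path.write_text("".join(genbank_record(*r) for r in records))
        return path

    return _make
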