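# altorf

A toolkit for discovering alternative open reading frames (AltORFs) on
annotated mature mRNAs and for downstream proteogenomics: building augmented
target/decoy protein search databases, post-processing peptide evidence, and
profiling cross-species conservation of the predicted alternative proteome.

An AltORF here is the region between an AUG codon and the nearest downstream
in-frame stop codon that is distinct from the annotated reference ORF
(RefORF).  AltORFs may sit in the 5'UTR, overlap the 5'UTR and the CDS,
lie inside the CDS, overlap the CDS and the 3'UTR, sit in the 3'UTR, or span
the entire CDS.  Scanning uses the first-AUG rule per stop-delimited slot in
each of the three sense-strand frames, keeps candidates regardless of Kozak
context or location, requires a minimum protein length (default 40 aa, stop
excluded), and excludes same-frame candidates that share the RefORF's stop
codon (N-terminal truncations/extensions).

## Modules

| module                | what it does |
|-----------------------|--------------|
| `altorf.transcript_io`| GenBank / FASTA+CDS-table transcript input; AltORF TSV tables; supplementary-spreadsheet dialect (XLSX); protein FASTA I/O |
| `altorf.core`         | AltORF scanner, frame assignment, location classification, translation, deduplication to distinct alternative proteins |
| `altorf.dbstats`      | database-level summaries: per-mRNA counts, location percentages, length medians, gene-level CDS-containment |
| `altorf.proteomics`   | target+decoy search FASTA, trypsin/P digestion, peptide-to-protein mapping with grouping/uniqueness, PEP filtering, coverage, N-terminal-acetylation TIS validation, co-expression, hypergeometric overlap enrichment |
| `altorf.conservation` | best-hit local alignment (BLOSUM62, 11/1 affine gaps) with Karlin–Altschul E-values; identity histograms and medians |
| `altorf.synthetic`    | seeded generators with planted ground truth, plus an independent brute-force scanning oracle |
| `altorf.cli`          | `altorf` command-line front-end |

## CLI

```bash
# enumerate AltORFs from annotated transcripts
altorf build-db --input transcripts.gb --min-len 40 --out altorfs.tsv --proteins altprot.fasta
altorf build-db --fasta transcripts.fasta --cds-table cds.tsv --out altorfs.tsv

# summarize a database
altorf stats --db altorfs.tsv --transcripts transcripts.gb --out summary.tsv

# proteomics search space and evidence layer
altorf search-fasta --reference ref.fasta --alternative alt.fasta --contaminants cont.fasta --out search.fasta
altorf map-peptides --peptides peptides.tsv --db search.fasta --out detections.tsv

# conservation profiling
altorf conserve --query yeast_alt.fasta --subject human_alt.fasta --evalue 1e-4 --out hits.tsv

# synthetic fixtures with ground truth
altorf simulate transcripts --seed 3 --out sim/
altorf simulate peptides --seed 3 --out simpep/

# dialect validation
altorf io validate altorfs.tsv
```

All flags have `key=value` equivalents in a plain-text config file passed via
`altorf --config run.cfg <subcommand>`; flags override config.  Exit codes:
0 success, 1 validation error, 2 I/O error.

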