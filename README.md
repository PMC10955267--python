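# trialign

Local alignment of **protein**, **nucleotide** and **bisulfite-converted**
query sequences against an FM-indexed subject collection — one engine, three
search domains, with BLAST-style significance statistics and optional LCA
taxonomic binning.

## Who it is for

Homology search and metagenomic read classification need *local* alignments
(the best-scoring substring pair), many hits per query, and significance
filtering — unlike read mappers, which compute one semi-global placement.
No established local aligner accepts reads from bisulfite sequencing
experiments, where unmethylated cytosines appear as thymines: such reads
need asymmetric scoring (subject C vs query T is not an error, but T vs C
is) and strand-family-aware indexing. `trialign` provides all three domains
behind one interface:

| domain      | index      | search     | analogous tools           |
|-------------|------------|------------|---------------------------|
| protein     | `mkindexp` | `searchp`  | blastp/blastx/tblastn/tblastx |
| nucleotide  | `mkindexn` | `searchn`  | blastn/megablast          |
| bisulfite   | `mkindexbs`| `searchbs` | (no local-alignment equivalent) |

## Method

**Index.** Subjects are framed per domain — protein: six-frame translation
of nucleotide input, then reduction to a 10-group amino-acid alphabet
(li10 default, mu10 optional); nucleotide: dna4 (N replaced by a seeded
random base); bisulfite: every subject is emitted twice into an artificial
six-letter alphabet whose first three ranks collapse C=T and last three
collapse G=A, so a single FM-index serves reads from both strand families.
The concatenated reduced text (separator rank 0 between blocks) is indexed
by a BWT with checkpointed occurrence counts and a sampled suffix array.

**Search.** Reduced query frames (2 for nucleotide: forward + reverse
complement; 4 for bisulfite: fwd/rc × CT/GA; 1 or 6 for protein) are split
into seeds of length *L* every *offset* positions. Seeds are searched
backward in the FM-index, allowing `delta ∈ {0,1}` mismatches restricted to
the seed's second half (*half-exact seeding*), elongated while they occur
more than `max_occ` times (*adaptive seeding*), and optionally retried with
more sensitive parameters only when a query had no verified hit
(*iterative search*). Candidates are re-scored in the unreduced space with
a gapless X-drop extension, then extended by exact affine-gap
Smith–Waterman (no X-drop) of the full unreduced query frame against the
subject window, using BLOSUM62 (gaps −11/−1), the nucleotide scheme
{2, −3, −2, −5}, or the asymmetric bisulfite variants of the latter.

**Statistics.** Raw scores S become bit-scores S′ = (λS − ln K)/ln 2 and
e-values E = m·n·2^(−S′) (query length m, total database residues n).
Reporting thresholds can be given as an e-value (default 0.01), a bit-score
or a percent identity; the bit-score equivalent of an e-value cut-off is
⌊log₂(m·n/E)⌋.

## Worked example

```bash
# 100 kb toy genome + 200 fully bisulfite-converted reads (no downloads)
trialign simulate --seed 11 --genome-length 100000 --read-count 200 \
    --read-length 100 --bisulfite four-type --conversion-rate 1.0 --out-prefix toy
trialign mkindexbs -d toy.genome.fasta -i toy.lba
trialign searchbs -q toy.reads.fastq -i toy.lba -o hits.tsv --approximate-bs-stats
head -2 hits.tsv
```

```
read0	chr1	77.000	100	23	0	1	100	56967	57066	2.12e-48	181.6
read0	chr1	56.000	50	18	1	90	41	19966	20011	1.06e-04	36.5
```

Columns are the standard 12 BLAST-tabular fields. The first row is
`read0`'s true origin: 23 of its 100 bases are literal C→T conversions
(77% identity), yet the raw score is the maximal 200 (bit-score 181.6,
e-value 2.12e-48) because the CT matrix scores subject-C/query-T pairs as
matches — conversion is not an error. The second row is a weak secondary
hit on the opposite strand (qstart > qend marks reverse-frame hits).
`--outfmt sam` writes SAM with soft-clipped local hits and `ZR:Z:CT|GA`
tags; `--outfmt pairwise` writes human-readable blocks.

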