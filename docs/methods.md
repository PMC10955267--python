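# Methods

## Model and procedure

`trialign` computes gapped local alignments of short query sequences
against an indexed subject collection in three domains (protein,
nucleotide, bisulfite) using the classical seed-and-extend architecture:

1. **Framing.** Queries and subjects are viewed through domain-specific
   *frames*. Nucleotide queries get a forward and a reverse-complement
   frame; nucleotide input to the protein domain is translated in all six
   reading frames (standard genetic code; trailing partial codons dropped;
   any codon containing N translates to X; stop codons translate to a
   dedicated symbol). Bisulfite queries get four frames: forward and
   reverse-complement, each reduced in both conversion directions.
2. **Reduction.** Seeding operates in a reduced alphabet for speed and
   sensitivity: li10/mu10 ten-group amino-acid alphabets (protein), dna4
   (nucleotide; N replaced by a seeded random base) and the six-letter
   bisulfite alphabet, whose ranks {0,1,2} encode A, C=T, G and ranks
   {3,4,5} encode G=A, C, T. Subjects in the bisulfite domain are emitted
   twice (a CT-reduced and a GA-reduced copy), so one FM-index serves both
   strand families; the two rank images are disjoint, which automatically
   routes each query frame to the matching subject copy. The central
   correctness property (tested): converting any subset of Cs to Ts leaves
   the CT reduction of a sequence unchanged, and mirrored for G→A.
3. **Seeding.** Fixed-length windows of the reduced frames are searched
   backward in a BWT/FM-index. One mismatch may be allowed, restricted to
   the second half of the seed (*half-exact*), which is consumed first by
   backward search so mismatch branches are pruned early. Seeds occurring
   more than `max_occ` times are elongated leftward through the query
   (*adaptive*), stopping at the bound, at query exhaustion, or at the last
   non-empty interval. An optional *iterative* mode runs a cheap pass first
   and a sensitive pass only for queries without verified hits.
4. **Verification and extension.** Because reduction admits false
   positives, every located hit is re-scored in the unreduced space by a
   gapless extension through the seed region (X-drop 16). Survivors are
   extended by exact affine-gap Smith–Waterman — full matrix, no X-drop —
   of the whole unreduced query frame against a subject window (seed region
   ± query length + 16). In the bisulfite domain hits are scored with the
   asymmetric preset matching their subject copy: the CT matrix scores
   subject-C/query-T as a match while T/C stays a mismatch (mirrored for
   GA). A fully converted read therefore scores exactly like its
   unconverted original.
5. **Statistics and reporting.** Raw scores are converted to bit-scores
   S′ = (λS − ln K)/ln 2 with per-preset Karlin–Altschul constants and to
   e-values E = m·n·2^(−S′), where m is the original query length (in
   nucleotides for translated searches — this convention reproduces all
   four pre-computed benchmark thresholds) and n the total residue count of
   the original subjects: bisulfite duplication and translation frames are
   indexing artifices, not database content. Results failing the active
   thresholds are dropped; the rest are sorted by bit-score (ties: subject
   id, subject start) and capped (default 25 per query). The bit-score
   equivalent of an e-value cut-off is ⌊log₂(m·n/E)⌋ — flooring is the only
   convention consistent with all four published threshold values.
   Effective-length (edge-effect) corrections and composition-based
   statistics are deliberately omitted.

## Parameters

| parameter | protein | nucleotide | bisulfite | notes |
|---|---|---|---|---|
| seed length (reduced symbols) | 10 | 14 | 16 | smaller alphabets need longer seeds for specificity |
| seed offset | 5 | 7 | 8 | distance between seed begin positions |
| seed delta | 1 | 1 | 1 | mismatch restricted to the second half |
| adaptive max. occurrences | 64 | 64 | 64 | |
| scoring | BLOSUM62, gaps −11/−1 | {2,−3}, gaps −5/−2 | nucleotide + asymmetric C→T / G→A | gap run of g costs open + g·extend |
| λ, K | 0.267, 0.041 | 0.625, 0.41 | 0.625, 0.41 | published gapped constants |
| e-value cut-off | 0.01 | 0.01 | 0.01 | `-e`; `--bit-score-threshold` and `--pct-identity` optional |
| hits per query | 25 | 25 | 25 | `-n` |

Profiles: `fast` doubles the offset, sets delta 0 and enables the iterative
fallback to the default parameters; `sensitive` sets offset = ⌈L/3⌉. The
per-domain default seed parameters are this implementation's choices,
tuned for the reduced-alphabet sizes, and are all exposed as flags.

The bisulfite Karlin–Altschul constants are the plain nucleotide ones: no
published constants exist for asymmetric conversion-aware matrices, so
bisulfite e-values are approximate. `searchbs` therefore refuses to run
unless the user supplies an explicit `--bit-score-threshold` or
acknowledges the approximation with `--approximate-bs-stats`.

## Index structures and numerical choices

* Suffix array by numpy prefix-doubling (O(n log² n)); no native
  dependencies, adequate to tens of megabases.
* BWT occurrence counts checkpointed every 64 positions; suffix-array
  samples every 16 text positions. Sequence blocks are separated by a
  single reserved rank (0, lexicographically smallest); patterns never
  contain it, so matches cannot cross sequence boundaries. Block-start
  positions are always added to the suffix-array sample: with repeated
  separator ranks the LF mapping is only exact for content symbols, and
  forced block-start samples guarantee locate walks never step across a
  separator.
* Smith–Waterman traceback prefers diagonal, then subject-gap, then
  query-gap; the reported cell is the first maximum in row-major order, so
  results are deterministic and independent of hit-input order.
* Seed hits are deduplicated per (query frame, subject frame, diagonal),
  keeping the longest match; alignments deduplicated on identical
  (subject, query range, subject range).
* Percent identity counts literal residue matches: a converted bisulfite
  base is a match for *scoring* but a mismatch for *identity*, mirroring
  how such alignments read in BLAST-tabular output.
* N replacement (dna4/bs6 reductions) draws from a generator seeded by the
  archive seed (index side) or by (run seed, query ordinal) (query side),
  so index builds and searches are reproducible and thread-count
  invariant. Worker threads process fixed query chunks and results are
  merged in input order; output bytes are identical for any `-t`.
* Rare amino acids reduce to their most common resolution (B→N group,
  Z→Q/E group, J→L group, U→C group, O→K group); X and the stop symbol get
  dedicated reduced ranks, and every substitution score involving a stop is
  −16 so alignments never match through stops. BLOSUM62 rows for J/U/O use
  the L/C/K rows.

## What the synthetic generator emulates — and what it does not

`trialign.synthetic` produces i.i.d. random genomes/proteomes at a chosen
GC fraction, uniformly placed reads on both strands with i.i.d.
substitution errors, in-silico bisulfite conversion (per-cytosine
conversion probability, default 0.99, in CT or GA direction; a
`uniform-strand` mode converts whole reads one way, and a `four-type` mode
draws the four bisulfite read types uniformly), and random rooted
taxonomies with ground-truth parent maps. It does **not** model genomic
repeats, compositional bias, indels, quality-dependent errors, CpG-context
methylation (conversion is applied to every cytosine regardless of
methylation state), or realistic taxon abundances. Passing tests therefore
demonstrate algorithmic correctness — exact index semantics, scoring
invariances, full recovery of clean reads — not sensitivity on real,
repeat-rich data.

Default problem sizes used by the tests and the acceptance script: 1 Mbp
genome with 500 × 100 bp reads for the bisulfite recovery check; 100 kb
genomes with 500 × 40 bp reads (nucleotide/bisulfite) and a 50 kaa
proteome with 500 × 24 aa reads (protein) for the sensitivity floors.

## Degenerate inputs and edge behavior

Empty queries yield no hits (not an error); frames shorter than the seed
length produce no windows; unknown characters encode to the wildcard rank
and never fail; RNA input folds U to T. Empty subject files, protein input
to the nucleotide/bisulfite builders, cyclic taxonomies, truncated
archives, wrong archive magic and version mismatches raise distinct typed
errors surfaced as exit code 2 by the CLI (usage errors exit 1).

## Known limitations

* Bisulfite e-values inherit nucleotide constants (see above); the CLI
  makes this explicit.
* Full-matrix Smith–Waterman without X-drop favors short reads; very long
  queries pay O(len(query) × window) per hit.
* `inverse_bwt` is a single-sequence diagnostic; multi-sequence
  reconstruction is not supported (locate does not need it).
* SAM output is defined for the nucleotide and bisulfite domains only —
  translated-coordinate SAM semantics are not well defined.
* The archive format stores whole arrays in memory; no memory-mapped or
  compressed-BWT variants.
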