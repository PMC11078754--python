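# Methods

## Scope

`ambiquant` quantifies reads over repetitive features under explicit,
comparable treatments of mapping ambiguity. It covers: repeat/gene annotation
ingestion, SAM alignment ingestion with read/fragment classification,
fractional TE-group coverage, gene counting under three strategies, 3' read
trimming, a synthetic genome/read generator with an exhaustive stand-in
aligner, and a reproducible pipeline layer with a thin CLI.

## Annotation model

Coordinates are 0-based half-open throughout the library; GTF (1-based,
closed) is converted on parsing.

**Repeats.** Input dialects are BED6 (`chrom start end name score strand`)
and a RepeatMasker-style TSV (`chrom start end name ...`). Parsing errors
carry the file name and 1-based line number. Copies sharing a name on one
chromosome are merged into one entry when they overlap or are exactly
adjacent (end == start under half-open coordinates); a 1-bp gap keeps them
separate, and different names never merge. The merged copies of one name form
a *TE group*; group coverage is the quantity of interest, so fragmented
annotation entries of one element are not double-counted.

**Clades.** An optional name → clade table assigns each group the *youngest*
clade among its labels, under a configurable youngest-first ordering
(default: Homo, Hominoidea, Catarrhini, Simiiformes, Primates,
Euarchontoglires, Boreoeutheria, Eutheria, Theria, Mammalia, Amniota,
Tetrapoda — a standard human-lineage ladder). Labels missing from the
ordering are an error; groups without any label carry no clade and are
excluded from clade aggregation.

**Genes.** GTF is parsed through gffutils (in-memory database). The gene
length `L_g` is the genomic *span* (gene start to gene end, introns
included), not the exon-length sum; exon records drive read-to-gene
assignment. The biotype comes from `gene_type`/`gene_biotype`. Orphan exons
(no gene record) synthesize a spanning gene with a warning.

## Alignment ingestion

Records are grouped by query name over a whole SAM file. Unmapped records,
records on references excluded by the filter, and exact duplicates
(position, strand, CIGAR) are removed *before* multiplicity is computed, so a
read whose only surviving mapping passes the filter is a unimapper.
Multiplicity is the retained record count; the NH tag is cross-checked and
disagreements are counted, never trusted.

The default ChIP-style reference filter keeps `^chr([0-9]+|X|Y)$`
(drops chrM and scaffolds/patches). For paired (RNA-seq style) input, only
records with the proper-pair flag are used and mates are joined by mutual
POS/PNEXT concordance; fragments with a missing mate are dropped and counted.

Aligned reference blocks are derived from the CIGAR: M/=/X and D consume and
stay within a block, N splits blocks (spliced segments contribute no intronic
span), S/I/H/P consume no reference. The read length `L_r` includes
soft-clipped bases.

## TE group coverage

For group K:

    C_K = Σ_{k∈K} Σ_{r∈Q} Σ_{r_i∈M_r} [I_k(r_i)/|M_r|] · (l_{k,r_i}/L_r)

with `l_{k,r_i}` the aligned-block overlap of mapping `r_i` with copy `k`.
Coverage is reported per group and read class (unimapper / multimapper /
combined; the combined value equals the sum of the strata). On
non-overlapping annotations each read contributes at most one unit in total.
The per-group multimapper read fraction and the share of groups at or above
a threshold (default 0.70) are reported alongside; groups touched by no read
have an undefined fraction and are excluded from that denominator.

Terms are accumulated exactly: per-group sums use `math.fsum`, so the
reported value is the correctly rounded value of the defining sum regardless
of read order.

## Gene counting strategies

A mapping (pair) is assigned gene set S = all genes with ≥ 1 exon base
overlapped by either mate's aligned blocks (union mode). Only |S| = 1 counts;
|S| = 0 (no feature) and |S| ≥ 2 (ambiguous, e.g. nested or overlapping
genes) count to nothing — matching HTSeq-count union mode with
`--nonunique none`.

- `H_g` (unique-only): fragments with exactly one mapping, singleton S.
- `C_g` (fractional): each mapping contributes `1/|M_f|` when its S is a
  singleton; a fragment spreads at most one unit of count.
- `R_g` (random selection): one mapping per fragment chosen uniformly
  (unimappers consume no randomness), then the unique rule; deterministic
  under a fixed seed, with `E[R_g] = C_g`.

Expression divides counts by the span length `L_g`. A gene is *expressed*
iff `C_g > 0`; *under-quantified* iff `(C_g/L_g)/(H_g/L_g) > 2` (strict),
with `H_g = 0 ∧ C_g > 0` treated as an infinite ratio. `C_g` is also exported
rounded to the nearest integer (half away from zero) for count-based
downstream tools. Top-N protein-coding rankings (default N = 50/100/200) by
`expr_H` or `expr_C` use a deterministic gene-id tie-break and warn when
fewer than N expressed genes exist.

## 3' trimming

Reads are truncated to a target length keeping the 5' end (3' trimming);
shorter reads pass unchanged. Paired files are trimmed in lockstep.

## Synthetic data generator

A genome is unique i.i.d. random background plus placements:

- repeat families: `n_copies` copies of one random consensus, each copy with
  i.i.d. per-site substitutions at rate `divergence` (substitutions only —
  no indels — so alignment truth stays exact);
- gene families: paralogs of one coding consensus, optionally split into
  equal exons separated by per-paralog random introns (only exons drive
  multimapping).

Placements are shuffled and separated by background gaps of at least
2 × read length (and gaps exceed the paired insert window in the presets),
so a read internal to one placement cannot straddle or pair across another.
Everything derives from one integer seed; regeneration is byte-identical.

Read simulation draws error-free reads (an error rate is available) from the
whole genome (`uniform`), uniformly chosen repeat copies (`from_repeats`), or
round-robin over genes (`from_genes`), recording per-read truth (position,
strand, source). Paired mode draws fragment lengths from a truncated normal.

## Exhaustive stand-in aligner

The aligner reports *every* position, on both strands, where a read matches
the genome with at most `max_mismatches` substitutions. Candidate positions
come from a pigeonhole k-mer index: with `max_mismatches + 1` disjoint exact
seeds of length `k = min(32, read_length // (max_mismatches + 1))`, any hit
within the budget leaves at least one seed exact, so the seeded search is
lossless; candidates are verified by vectorised Hamming comparison. A
brute-force all-position scan with the same contract is provided and used as
the oracle in tests. Output is SAM via pysam with NH/NM tags; the leftmost
hit is primary, the rest secondary, all with equal mapping quality. In paired
mode, mate hits are combined into FR-oriented pairs with an insert inside a
configurable window; only concordant pairs are emitted, and fragments
without one are written unmapped.

Three presets exercise the designed biases: `young_vs_old_te` (20 × 300 bp
copies at divergence 0.005 vs 0.15, 4000 SE 100 bp reads, 3 mismatches),
`paralog_genes` (4 paralogs at 0.005 plus 20 unique genes, 1500 2×75 bp
pairs, 2 mismatches), and `trim_series` (8 × 400 bp copies at 0.04,
2000 2×100 bp pairs realigned at 25/50/75/100 bp, 2 mismatches).

## Numerical and reproducibility choices

- Exactly rounded summation (`math.fsum`) for coverage accumulation.
- All randomness flows through `numpy.random.default_rng` seeded explicitly;
  fixed seeds reproduce FASTA/BED/GTF/FASTQ/SAM/TSV outputs byte for byte.
- Pipeline runs echo their resolved configuration (`run_config.yaml`) next to
  their outputs and log bookkeeping counters (records read, filtered,
  duplicates, classification counts).
- TSV outputs use '.' for undefined values and `%.6g` floats.

## Limitations

- The stand-in aligner is substitution-only: no indels, splicing, or quality-
  aware scoring; it is meant for controlled experiments and oracle testing,
  not production read mapping.
- The generator models divergence as i.i.d. substitutions; real repeat
  families have indels, truncations and CpG-biased mutation spectra.
- Gene assignment implements union mode with the `--nonunique none` rule
  only; intersection modes and EM-based reassignment are out of scope.
- Single-chromosome synthetic genomes; multi-reference handling is exercised
  only through annotation/filtering, not the aligner.
- The under-quantification flag compares two strategies on one library; it is
  a descriptive diagnostic, not a statistical test with error control.
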