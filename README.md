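# ambiquant

Multimapper-aware quantification of sequencing reads over repetitive genomic
features: fractional transposable-element (TE) group coverage for ChIP-seq and
three gene-counting strategies for RNA-seq, together with a synthetic-data
generator and an exhaustive stand-in aligner that make every result verifiable
against known truth.

## The problem

A large share of short sequencing reads aligns equally well to several genomic
positions ("multimappers"), because genomes are full of near-identical
sequence: young transposable-element families, paralogous genes, segmental
duplications. Standard pipelines discard these reads or keep only one
arbitrary alignment. Both choices bias results in a structured way: young,
low-divergence repeat families lose almost all of their coverage, and genes
with close paralogs are systematically under-quantified relative to
single-copy genes. `ambiquant` implements and compares the three common
treatments so the size of the bias can be measured directly.

## What it computes

**TE group coverage.** For a TE group *K* (all merged annotation entries
sharing a repeat name), reads *Q*, and the set *M_r* of loci read *r* maps to:

```
C_K = Σ_{k∈K} Σ_{r∈Q} Σ_{r_i∈M_r}  [ I_k(r_i) / |M_r| ] · ( l_{k,r_i} / L_r )
```

where `I_k(r_i)` indicates that mapping `r_i` overlaps copy *k*, `l_{k,r_i}`
is the number of aligned bases of that mapping inside the copy, and `L_r` is
the read length. Each read spreads at most one unit of count over the copies
it touches, down-weighted by its multiplicity. Coverage is stratified into
unimapper / multimapper / combined classes and can be aggregated by repeat age
(clade).

**Gene counts under three strategies.** A mapping's gene set *S* is every
gene with an exon overlapped by at least one aligned base of either mate
(union mode); a mapping counts only when *S* is a singleton — ambiguous and
feature-less mappings count to nothing:

- `H_g` — unique-only baseline: only single-mapping fragments contribute
  (HTSeq-count union mode, `--nonunique none` semantics);
- `C_g` — fractional: every mapping of fragment *f* contributes
  `I_g(f_i) / |M_f|`;
- `R_g` — random selection: one mapping kept uniformly at random per
  fragment; `E[R_g] = C_g`.

Expression is count divided by the gene's genomic span length `L_g`. A gene
is *expressed* when `C_g > 0` and *under-quantified* when
`(C_g/L_g) / (H_g/L_g) > 2` (strict; `H_g = 0` with `C_g > 0` counts as an
infinite ratio).

**Synthetic truth.** `ambiquant.synthetic` builds genomes with tunable repeat
families, paralogous gene families and unique background; simulates reads
with recorded origin; and aligns them with an exhaustive substitution-only
aligner that reports *every* position matching within a mismatch budget —
so mapping multiplicity is a pure function of genome structure, and all
statistics can be checked against brute-force oracles.

## Worked example

Generate a fixture with a young (0.5% divergence) and an old (15% divergence)
repeat family, 20 copies × 300 bp each, 4000 single-end 100 bp reads:

```
$ ambiquant --quiet simulate --preset young_vs_old_te --seed 7 --out demo/fixture
wrote young_vs_old_te fixture to demo/fixture

$ ambiquant --quiet te-coverage \
    --repeats demo/fixture/repeats.bed --clades demo/fixture/clades.tsv \
    --sam demo/fixture/alignments.sam --out demo/te_run
{
  "threshold": 0.7,
  "n_groups_total": 2,
  "n_groups_touched": 2,
  "n_groups_at_or_above": 1,
  "share_at_or_above_among_touched": 0.5
}

$ head -7 demo/te_run/te_coverage.tsv
group    clade     class        coverage  n_reads_touching  multimapper_read_fraction
OldTE    Eutheria  unimapper    2054      2054              0
OldTE    Eutheria  multimapper  0         0                 0
OldTE    Eutheria  all          2054      2054              0
YoungTE  Homo      unimapper    0         0                 1
YoungTE  Homo      multimapper  1946      1946              1
YoungTE  Homo      all          1946      1946              1
```

Every read from the young family is a multimapper: a unique-only analysis
reports zero coverage for it while the fractional statistic recovers all
1946 reads. The gene-count counterpart:

```
$ ambiquant --quiet simulate --preset paralog_genes --seed 7 --out demo/genes
$ ambiquant --quiet gene-count --gtf demo/genes/genes.gtf \
    --sam demo/genes/alignments.sam --out demo/gene_run
24 genes, 24 expressed, 4 under-quantified

$ head -6 demo/gene_run/gene_counts.tsv
gene_id  biotype         length  H   C     C_rounded  R   expr_H      expr_C     expressed  under_quantified
PARA_01  protein_coding  1200    0   60.5  61         56  0           0.0504167  True       True
PARA_02  protein_coding  1200    0   64.5  65         57  0           0.05375    True       True
PARA_03  protein_coding  1200    8   65.5  66         69  0.00666667  0.0545833  True       True
PARA_04  protein_coding  1200    0   61.5  62         70  0           0.05125    True       True
UNIQ01   protein_coding  1200    63  63    63         63  0.0525      0.0525     True       False
```

The four designed paralogs — and only they — are flagged as under-quantified:
unique-only counting sees 0–8 of their ~60 fragments each, while all 20
single-copy genes get identical counts under every strategy.

The same analyses are available as library calls; see `examples/` for three
short narrative scripts (TE coverage bias, gene under-quantification, and the
read-length trend, where trimming the same library from 100 bp to 25 bp raises
the multimapping fragment fraction from 0% to 69%).

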