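"""Synthetic repeat-rich genomes, read simulation with known truth, and an
exhaustive stand-in aligner.

The generator emulates the genomic structure that produces multimappers in
real libraries: "young" repeat families (many near-identical copies, per-site
divergence from the family consensus around 0-1%), "old" families (10-20%
divergence), paralogous gene families with tunable identity, and unique random
background.  Divergence is substitution-only — no indels — which keeps the
stand-in aligner exact and every read's true origin unambiguous.

The aligner reports *every* genomic position, on both strands, where a read
matches with at most ``max_mismatches`` substitutions, so mapping multiplicity
is a pure function of genome structure.  A pigeonhole k-mer seed index
accelerates the search; its results equal a brute-force scan over all
positions, which is also provided (and used as the oracle in tests).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from .core import GeneModel, GenomicInterval, InputError, RepeatCopy, SizingError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Specifications


@dataclass(slots=True)
class RepeatFamilySpec:
    """A repeat family: ``n_copies`` copies of a random consensus, each with
    i.i.d. per-site substitutions at rate ``divergence``."""

    name: str
    consensus_length: int
    n_copies: int
    divergence: float
    clade: str | None = None


@dataclass(slots=True)
class GeneFamilySpec:
    """A paralogous gene family; ``n_paralogs`` copies of a coding consensus.

    With ``n_exons > 1`` the coding sequence is split into equal exons
    separated by introns of ``intron_length`` unique random sequence (introns
    are independent per paralog, so only exons drive multimapping).
    """

    name: str
    n_paralogs: int
    coding_length: int
    divergence: float
    n_exons: int = 1
    intron_length: int = 200
    biotype: str = "protein_coding"


@dataclass(slots=True)
class SyntheticSpec:
    """Complete description of a synthetic genome and its read library."""

    background_length: int
    repeat_families: list[RepeatFamilySpec] = field(default_factory=list)
    gene_families: list[GeneFamilySpec] = field(default_factory=list)
    read_length: int = 100
    paired: bool = False
    fragment_mean: float = 250.0
    fragment_sd: float = 25.0
    n_reads: int = 1000
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for fam in self.repeat_families:
            if not (0.0 <= fam.divergence < 0.5):
                raise InputError(f"divergence must be in [0, 0.5): {fam.name}")
            if fam.consensus_length <= 0 or fam.n_copies <= 0:
                raise InputError(f"non-positive sizes for family {fam.name}")
        for fam in self.gene_families:
            if not (0.0 <= fam.divergence < 0.5):
                raise InputError(f"divergence must be in [0, 0.5): {fam.name}")
            if fam.coding_length <= 0 or fam.n_paralogs <= 0 or fam.n_exons <= 0:
                raise InputError(f"non-positive sizes for family {fam.name}")
        if self.background_length <= 0 or self.read_length <= 0 or self.n_reads <= 0:
            raise InputError("background_length, read_length and n_reads must be > 0")
        if not (0.0 <= self.error_rate < 1.0):
            raise InputError("error_rate must be in [0, 1)")


@dataclass(slots=True)
class SyntheticGenome:
    """A built genome with its annotations and placement truth."""

    chrom: str
    sequence: str
    repeat_copies: list[RepeatCopy]
    te_clades: dict[str, str]
    genes: list[GeneModel]
    layout: pd.DataFrame  # one row per placement: kind, name, start, end
    repeat_consensus: dict[str, str]
    gene_consensus: dict[str, str]
    spec: SyntheticSpec

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(slots=True)
class SimRead:
    name: str
    sequence: str
    quality: str


# ---------------------------------------------------------------------------
# Genome construction


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    if divergence == 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < divergence
    idx = np.nonzero(hit)[0]
    if idx.size:
        # substitute with one of the three *other* bases
        cur = np.searchsorted(np.sort(_BASES), arr[idx])  # ACGT are sorted
        shift = rng.integers(1, 4, size=idx.size)
        arr[idx] = np.sort(_BASES)[(cur + shift) % 4]
    return arr.tobytes().decode()


def build_genome(spec: SyntheticSpec, chrom: str = "chr1") -> SyntheticGenome:
    """Assemble the synthetic genome deterministically from ``spec.seed``.

    Placements (repeat copies and genes) are shuffled and separated by unique
    random background; every gap is at least ``2 * read_length`` so reads
    internal to one placement cannot straddle another.
    """
    rng = np.random.default_rng(spec.seed)

    repeat_consensus = {f.name: _random_seq(rng, f.consensus_length)
                        for f in spec.repeat_families}
    gene_consensus = {f.name: _random_seq(rng, f.coding_length)
                      for f in spec.gene_families}

    placements: list[dict] = []
    for fam in spec.repeat_families:
        for i in range(fam.n_copies):
            placements.append({
                "kind": "repeat", "family": fam.name,
                "name": f"{fam.name}#{i + 1}",
                "seq": _mutate(repeat_consensus[fam.name], fam.divergence, rng),
                "exon_offsets": None,
            })
    for fam in spec.gene_families:
        exon_sizes = _split_sizes(fam.coding_length, fam.n_exons)
        for i in range(fam.n_paralogs):
            gene_id = fam.name if fam.n_paralogs == 1 else f"{fam.name}_{i + 1:02d}"
            coding = _mutate(gene_consensus[fam.name], fam.divergence, rng)
            seq_parts, offsets, pos = [], [], 0
            coding_pos = 0
            for j, size in enumerate(exon_sizes):
                if j > 0 and fam.intron_length > 0:
                    seq_parts.append(_random_seq(rng, fam.intron_length))
                    pos += fam.intron_length
                seq_parts.append(coding[coding_pos:coding_pos + size])
                offsets.append((pos, pos + size))
                pos += size
                coding_pos += size
            placements.append({
                "kind": "gene", "family": fam.name, "name": gene_id,
                "seq": "".join(seq_parts), "exon_offsets": offsets,
                "biotype": fam.biotype,
            })

    order = rng.permutation(len(placements))
    placements = [placements[i] for i in order]

    min_gap = 2 * spec.read_length
    n_gaps = len(placements) + 1
    if spec.background_length < n_gaps * min_gap:
        raise SizingError(
            f"background_length={spec.background_length} too small: "
            f"{n_gaps} gaps of >= {min_gap} bp require at least {n_gaps * min_gap} bp"
        )
    base, extra = divmod(spec.background_length, n_gaps)
    gap_sizes = [base + (1 if i < extra else 0) for i in range(n_gaps)]

    parts: list[str] = []
    pos = 0
    repeat_copies: list[RepeatCopy] = []
    genes: list[GeneModel] = []
    layout_rows = []
    for i, pl in enumerate(placements):
        gap = _random_seq(rng, gap_sizes[i])
        parts.append(gap)
        pos += len(gap)
        start, end = pos, pos + len(pl["seq"])
        parts.append(pl["seq"])
        pos = end
        layout_rows.append({"kind": pl["kind"], "family": pl["family"],
                            "name": pl["name"], "chrom": chrom,
                            "start": start, "end": end})
        if pl["kind"] == "repeat":
            repeat_copies.append(RepeatCopy(
                name=pl["family"],
                interval=GenomicInterval(chrom, start, end, "+"),
            ))
        else:
            exons = [GenomicInterval(chrom, start + a, start + b, "+")
                     for a, b in pl["exon_offsets"]]
            genes.append(GeneModel(
                gene_id=pl["name"],
                span=GenomicInterval(chrom, start, end, "+"),
                exons=exons,
                biotype=pl["biotype"],
            ))
    parts.append(_random_seq(rng, gap_sizes[-1]))

    te_clades = {f.name: f.clade for f in spec.repeat_families if f.clade}
    genes.sort(key=lambda g: g.gene_id)
    return SyntheticGenome(
        chrom=chrom,
        sequence="".join(parts),
        repeat_copies=sorted(repeat_copies, key=lambda c: c.interval.start),
        te_clades=te_clades,
        genes=genes,
        layout=pd.DataFrame(
            layout_rows,
            columns=["kind", "family", "name", "chrom", "start", "end"],
        ).sort_values("start").reset_index(drop=True),
        repeat_consensus=repeat_consensus,
        gene_consensus=gene_consensus,
        spec=spec,
    )


def _split_sizes(total: int, n: int) -> list[int]:
    base, extra = divmod(total, n)
    return [base + (1 if i < extra else 0) for i in range(n)]


# ---------------------------------------------------------------------------
# Read simulation


def simulate_reads(
    genome: SyntheticGenome,
    mode: str = "uniform",
    n_reads: int | None = None,
    rng: np.random.Generator | None = None,
    id_prefix: str = "sim",
) -> tuple[list, pd.DataFrame]:
    """Draw error-free (by default) reads with recorded truth.

    Modes: ``uniform`` draws fragments anywhere on the chromosome;
    ``from_repeats`` draws from uniformly chosen repeat copies;
    ``from_genes`` cycles round-robin over genes and draws from an exon large
    enough to hold the fragment (so every gene receives reads).  Paired mode
    draws the fragment length from a normal truncated to fit the source
    region, emitting properly oriented FR mates.  Returns single reads or
    (mate1, mate2) tuples plus one truth record per read/fragment.
    """
    spec = genome.spec
    n = n_reads if n_reads is not None else spec.n_reads
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    L = spec.read_length
    if L > genome.length:
        raise InputError("read_length exceeds genome length")

    if mode == "uniform":
        regions = [("background", 0, genome.length)]
        pick = lambda i: regions[0]
    elif mode == "from_repeats":
        regions = [(c.name, c.interval.start, c.interval.end)
                   for c in genome.repeat_copies]
        if not regions:
            raise InputError("genome has no repeat copies")
        pick = lambda i: regions[int(rng.integers(len(regions)))]
    elif mode == "from_genes":
        if not genome.genes:
            raise InputError("genome has no genes")
        gene_exons = [(g.gene_id, [(e.start, e.end) for e in g.exons])
                      for g in genome.genes]
        pick = None
    else:
        raise InputError(f"unknown simulation mode: {mode!r}")

    reads: list = []
    truth_rows = []
    for i in range(n):
        if mode == "from_genes":
            gene_id, exons = gene_exons[i % len(gene_exons)]
        for attempt in range(1000):
            if mode == "from_genes":
                es, ee = exons[int(rng.integers(len(exons)))]
                source, rs, re_ = gene_id, es, ee
            else:
                source, rs, re_ = pick(i)
            if spec.paired:
                flen = int(round(rng.normal(spec.fragment_mean, spec.fragment_sd)))
                flen = max(flen, L)
            else:
                flen = L
            if re_ - rs >= flen:
                break
        else:
            raise SizingError(
                f"could not place a {flen} bp fragment in region for {source}")
        start = int(rng.integers(rs, re_ - flen + 1))
        end = start + flen
        strand = "+" if rng.random() < 0.5 else "-"
        frag = genome.sequence[start:end]
        if strand == "-":
            frag = revcomp(frag)
        name = f"{id_prefix}_{i:06d}"
        if spec.paired:
            m1 = _with_errors(frag[:L], spec.error_rate, rng)
            m2 = _with_errors(revcomp(frag)[:L], spec.error_rate, rng)
            reads.append((SimRead(name, m1, "I" * len(m1)),
                          SimRead(name, m2, "I" * len(m2))))
        else:
            reads.append(SimRead(name, _with_errors(frag, spec.error_rate, rng),
                                 "I" * len(frag)))
        truth_rows.append({"read_id": name, "chrom": genome.chrom,
                           "start": start, "end": end, "strand": strand,
                           "source": source, "mode": mode})
    return reads, pd.DataFrame(truth_rows)


def _with_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0:
        return seq
    return _mutate(seq, rate, rng)


# ---------------------------------------------------------------------------
# Exhaustive alignment


class SeedIndex:
    """Pigeonhole exact k-mer index over one reference sequence."""

    def __init__(self, sequence: str, k: int):
        if k < 1:
            raise InputError(f"seed length must be >= 1, got {k}")
        self.k = k
        self.sequence = sequence
        self.array = np.frombuffer(sequence.encode(), dtype=np.uint8)
        index: dict[str, list[int]] = {}
        for i in range(len(sequence) - k + 1):
            index.setdefault(sequence[i:i + k], []).append(i)
        self.index = index

    def candidate_starts(self, read: str, n_seeds: int) -> set[int]:
        """Alignment start candidates from ``n_seeds`` disjoint exact seeds."""
        L = len(read)
        limit = len(self.sequence) - L
        cands: set[int] = set()
        for s in range(n_seeds):
            off = s * self.k
            seed = read[off:off + self.k]
            if len(seed) < self.k:
                break
            for p in self.index.get(seed, ()):
                start = p - off
                if 0 <= start <= limit:
                    cands.add(start)
        return cands


def _hits_one_strand(read: str, idx: SeedIndex, max_mismatches: int) -> list[tuple[int, int]]:
    L = len(read)
    rarr = np.frombuffer(read.encode(), dtype=np.uint8)
    out = []
    for start in idx.candidate_starts(read, max_mismatches + 1):
        nm = int(np.count_nonzero(idx.array[start:start + L] != rarr))
        if nm <= max_mismatches:
            out.append((start, nm))
    return out


def find_hits(read: str, idx: SeedIndex, max_mismatches: int) -> list[tuple[int, str, int]]:
    """All (position, strand, n_mismatches) hits of a read, both strands.

    Requires ``(max_mismatches + 1) * idx.k <= len(read)`` so the pigeonhole
    guarantee holds (one of the disjoint seeds must be exact in any hit).
    """
    if (max_mismatches + 1) * idx.k > len(read):
        raise InputError(
            f"seed length {idx.k} too large for {len(read)} bp reads with "
            f"{max_mismatches} mismatches")
    hits = [(p, "+", nm) for p, nm in _hits_one_strand(read, idx, max_mismatches)]
    hits += [(p, "-", nm) for p, nm in _hits_one_strand(revcomp(read), idx, max_mismatches)]
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def bruteforce_hits(read: str, sequence: str, max_mismatches: int) -> list[tuple[int, str, int]]:
    """All-position scan oracle; same contract as :func:`find_hits`."""
    garr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    out = []
    for strand, seq in (("+", read), ("-", revcomp(read))):
        rarr = np.frombuffer(seq.encode(), dtype=np.uint8)
        L = rarr.size
        n = garr.size - L + 1
        if n <= 0:
            continue
        counts = np.zeros(n, dtype=np.int64)
        for off in range(L):
            counts += garr[off:off + n] != rarr[off]
        for p in np.nonzero(counts <= max_mismatches)[0]:
            out.append((int(p), strand, int(counts[p])))
    out.sort(key=lambda h: (h[0], h[1]))
    return out


def pick_seed_length(read_length: int, max_mismatches: int) -> int:
    """Longest usable pigeonhole seed, capped at 32 to bound index size."""
    k = read_length // (max_mismatches + 1)
    if k < 1:
        raise InputError(
            f"{read_length} bp reads cannot support {max_mismatches} mismatches")
    return min(k, 32)


def _sam_header(chrom: str, length: int) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": chrom, "LN": length}],
        "PG": [{"ID": "ambiquant-exhaustive", "PN": "ambiquant"}],
    })


def _make_record(header, name, seq, qual, pos, strand, nm, nh, flag_extra=0):
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.reference_id = 0
    rec.reference_start = pos
    rec.mapping_quality = 30
    rec.cigarstring = f"{len(seq)}M"
    rec.flag = (16 if strand == "-" else 0) | flag_extra
    rec.query_sequence = revcomp(seq) if strand == "-" else seq
    rec.query_qualities = pysam.qualitystring_to_array(qual[::-1] if strand == "-" else qual)
    rec.set_tag("NH", nh)
    rec.set_tag("NM", nm)
    return rec


def exhaustive_align(
    reads: Sequence,
    genome: SyntheticGenome | str,
    max_mismatches: int,
    sam_path: str | Path,
    *,
    chrom: str = "chr1",
    paired: bool | None = None,
    insert_min: int | None = None,
    insert_max: int | None = None,
) -> dict:
    """Align reads exhaustively and write a SAM file with all hits.

    Every position (both strands) matching with at most ``max_mismatches``
    substitutions (no indels) is reported with identical mapping quality; the
    leftmost hit (by position, then strand) is primary, the rest secondary,
    and NH carries the hit count.  In paired mode, mate hits are combined into
    FR-oriented pairs whose insert lies within ``[insert_min, insert_max]``;
    only paired hits are emitted and fragments with no concordant pair (and
    single-end reads with no hit) are written as unmapped records.

    Returns a small summary dict (reads aligned, unmapped, records written).
    """
    if isinstance(genome, SyntheticGenome):
        sequence, chrom = genome.sequence, genome.chrom
    else:
        sequence = genome
    if paired is None:
        paired = bool(reads) and isinstance(reads[0], tuple)
    lengths = []
    for r in reads:
        if paired:
            lengths += [len(r[0].sequence), len(r[1].sequence)]
        else:
            lengths.append(len(r.sequence))
    if not lengths:
        raise InputError("no reads to align")
    k = pick_seed_length(min(lengths), max_mismatches)
    idx = SeedIndex(sequence, k)
    header = _sam_header(chrom, len(sequence))
    summary = {"aligned": 0, "unmapped": 0, "records": 0}

    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        if not paired:
            for read in reads:
                hits = find_hits(read.sequence, idx, max_mismatches)
                if not hits:
                    rec = pysam.AlignedSegment(header)
                    rec.query_name = read.name
                    rec.flag = 4
                    rec.query_sequence = read.sequence
                    rec.query_qualities = pysam.qualitystring_to_array(read.quality)
                    out.write(rec)
                    summary["unmapped"] += 1
                    summary["records"] += 1
                    continue
                summary["aligned"] += 1
                for j, (pos, strand, nm) in enumerate(hits):
                    rec = _make_record(header, read.name, read.sequence,
                                       read.quality, pos, strand, nm, len(hits),
                                       flag_extra=0 if j == 0 else 256)
                    out.write(rec)
                    summary["records"] += 1
        else:
            imin = insert_min if insert_min is not None else min(lengths)
            imax = insert_max if insert_max is not None else 10 * max(lengths)
            for m1, m2 in reads:
                h1 = find_hits(m1.sequence, idx, max_mismatches)
                h2 = find_hits(m2.sequence, idx, max_mismatches)
                pairs = _concordant_pairs(h1, h2, len(m1.sequence),
                                          len(m2.sequence), imin, imax)
                if not pairs:
                    for mate, flag in ((m1, 77), (m2, 141)):
                        rec = pysam.AlignedSegment(header)
                        rec.query_name = mate.name
                        rec.flag = flag
                        rec.query_sequence = mate.sequence
                        rec.query_qualities = pysam.qualitystring_to_array(mate.quality)
                        out.write(rec)
                        summary["records"] += 1
                    summary["unmapped"] += 1
                    continue
                summary["aligned"] += 1
                nh = len(pairs)
                for j, (p1, s1, nm1, p2, s2, nm2, tlen) in enumerate(pairs):
                    sec = 0 if j == 0 else 256
                    r1 = _make_record(header, m1.name, m1.sequence, m1.quality,
                                      p1, s1, nm1, nh,
                                      flag_extra=1 | 2 | 64 | sec
                                      | (32 if s2 == "-" else 0))
                    r2 = _make_record(header, m2.name, m2.sequence, m2.quality,
                                      p2, s2, nm2, nh,
                                      flag_extra=1 | 2 | 128 | sec
                                      | (32 if s1 == "-" else 0))
                    r1.next_reference_id = 0
                    r2.next_reference_id = 0
                    r1.next_reference_start = p2
                    r2.next_reference_start = p1
                    r1.template_length = tlen if p1 <= p2 else -tlen
                    r2.template_length = -tlen if p1 <= p2 else tlen
                    out.write(r1)
                    out.write(r2)
                    summary["records"] += 2
    return summary


def _concordant_pairs(h1, h2, l1, l2, imin, imax):
    """FR-oriented mate hit combinations with insert within the window."""
    pairs = []
    for p1, s1, nm1 in h1:
        for p2, s2, nm2 in h2:
            if s1 == "+" and s2 == "-" and p1 <= p2:
                tlen = (p2 + l2) - p1
            elif s1 == "-" and s2 == "+" and p2 <= p1:
                tlen = (p1 + l1) - p2
            else:
                continue
            if imin <= tlen <= imax:
                pairs.append((p1, s1, nm1, p2, s2, nm2, tlen))
    pairs.sort(key=lambda t: (min(t[0], t[3]), t[0], t[3], t[1]))
    return pairs


# ---------------------------------------------------------------------------
# File writers


def write_fasta(genome: SyntheticGenome, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.chrom}\n")
        for i in range(0, len(genome.sequence), width):
            fh.write(genome.sequence[i:i + width] + "\n")
    pysam.faidx(str(path))


def write_repeat_bed(genome: SyntheticGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in genome.repeat_copies:
            fh.write(f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}"
                     f"\t{c.name}\t0\t{c.interval.strand}\n")


def write_gene_gtf(genome: SyntheticGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genome.genes:
            attrs = f'gene_id "{g.gene_id}"; gene_type "{g.biotype}";'
            fh.write(f"{g.span.chrom}\tambiquant\tgene\t{g.span.start + 1}\t"
                     f"{g.span.end}\t.\t+\t.\t{attrs}\n")
            for e in g.exons:
                fh.write(f"{e.chrom}\tambiquant\texon\t{e.start + 1}\t{e.end}"
                         f"\t.\t+\t.\t{attrs} transcript_id \"{g.gene_id}.t1\";\n")


def write_clade_tsv(genome: SyntheticGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tclades\n")
        for name, clade in sorted(genome.te_clades.items()):
            fh.write(f"{name}\t{clade}\n")


def write_fastq(reads: Sequence, path: str | Path | tuple) -> None:
    """Write single reads to one FASTQ or pairs to (mate1, mate2) files."""
    if reads and isinstance(reads[0], tuple):
        p1, p2 = path
        with open(p1, "w") as f1, open(p2, "w") as f2:
            for m1, m2 in reads:
                f1.write(f"@{m1.name}/1\n{m1.sequence}\n+\n{m1.quality}\n")
                f2.write(f"@{m2.name}/2\n{m2.sequence}\n+\n{m2.quality}\n")
    else:
        with open(path, "w") as fh:
            for r in reads:
                fh.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str | Path) -> list[SimRead]:
    out = []
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            name = rec.name
            if name.endswith(("/1", "/2")):
                name = name[:-2]
            out.append(SimRead(name, rec.sequence,
                               rec.quality or "I" * len(rec.sequence)))
    return out


def write_spec_config(spec: SyntheticSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(spec), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Fixture presets


PRESETS = ("young_vs_old_te", "paralog_genes", "trim_series")


@dataclass(slots=True)
class FixtureBundle:
    """Paths and in-memory handles of a generated fixture."""

    preset: str
    out_dir: Path
    genome: SyntheticGenome
    paths: dict[str, object]
    truth: pd.DataFrame
    aligner_max_mismatches: int


def _young_vs_old_spec(seed: int) -> SyntheticSpec:
    return SyntheticSpec(
        background_length=20_000,
        repeat_families=[
            RepeatFamilySpec("YoungTE", 300, 20, 0.005, clade="Homo"),
            RepeatFamilySpec("OldTE", 300, 20, 0.15, clade="Eutheria"),
        ],
        read_length=100, paired=False, n_reads=4000, seed=seed,
    )


def _paralog_spec(seed: int) -> SyntheticSpec:
    fams = [GeneFamilySpec("PARA", 4, 1200, 0.005)]
    fams += [GeneFamilySpec(f"UNIQ{i:02d}", 1, 1200, 0.0) for i in range(1, 21)]
    return SyntheticSpec(
        background_length=20_000, gene_families=fams,
        read_length=75, paired=True, fragment_mean=200.0, fragment_sd=20.0,
        n_reads=1500, seed=seed,
    )


def _trim_spec(seed: int) -> SyntheticSpec:
    return SyntheticSpec(
        background_length=12_000,
        repeat_families=[RepeatFamilySpec("TrimFam", 400, 8, 0.04, clade="Primates")],
        read_length=100, paired=True, fragment_mean=220.0, fragment_sd=25.0,
        n_reads=2000, seed=seed,
    )


TRIM_LENGTHS = (25, 50, 75, 100)


def make_fixture(preset: str, out_dir: str | Path, seed: int = 7) -> FixtureBundle:
    """Generate a complete named fixture bundle under ``out_dir``.

    ``young_vs_old_te``: two 20-copy 300 bp repeat families at divergence
    0.005 (clade Homo) and 0.15 (clade Eutheria); 4000 single-end 100 bp reads
    drawn from the copies; aligned with up to 3 mismatches so near-identical
    young copies cross-map while old copies do not.

    ``paralog_genes``: one 4-paralog gene family at 0.5% divergence plus 20
    unique genes; 1500 proper 2x75 bp pairs drawn round-robin from exons;
    aligned with up to 2 mismatches.

    ``trim_series``: one 8-copy 400 bp family at 4% divergence; 2x100 bp pairs
    (1500 from the copies, 500 uniform) trimmed to 25/50/75/100 bp and aligned
    at each length with up to 2 mismatches.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if preset == "young_vs_old_te":
        spec = _young_vs_old_spec(seed)
        mm = 3
    elif preset == "paralog_genes":
        spec = _paralog_spec(seed)
        mm = 2
    elif preset == "trim_series":
        spec = _trim_spec(seed)
        mm = 2
    else:
        raise InputError(f"unknown preset {preset!r}; choose from {PRESETS}")

    genome = build_genome(spec)
    paths: dict[str, object] = {
        "fasta": out_dir / "genome.fa",
        "config": out_dir / "config.yaml",
        "truth": out_dir / "truth.tsv",
    }
    write_fasta(genome, paths["fasta"])
    write_spec_config(spec, paths["config"])
    if genome.repeat_copies:
        paths["repeats_bed"] = out_dir / "repeats.bed"
        paths["clades_tsv"] = out_dir / "clades.tsv"
        write_repeat_bed(genome, paths["repeats_bed"])
        write_clade_tsv(genome, paths["clades_tsv"])
    if genome.genes:
        paths["gtf"] = out_dir / "genes.gtf"
        write_gene_gtf(genome, paths["gtf"])

    rng = np.random.default_rng(spec.seed + 1)
    if preset == "young_vs_old_te":
        reads, truth = simulate_reads(genome, "from_repeats", rng=rng)
        paths["fastq"] = out_dir / "reads.fastq"
        write_fastq(reads, paths["fastq"])
        paths["sam"] = out_dir / "alignments.sam"
        exhaustive_align(reads, genome, mm, paths["sam"])
    elif preset == "paralog_genes":
        reads, truth = simulate_reads(genome, "from_genes", rng=rng)
        paths["fastq"] = (out_dir / "reads_1.fastq", out_dir / "reads_2.fastq")
        write_fastq(reads, paths["fastq"])
        paths["sam"] = out_dir / "alignments.sam"
        exhaustive_align(reads, genome, mm, paths["sam"],
                         insert_min=spec.read_length, insert_max=400)
    else:  # trim_series
        rep_reads, t1 = simulate_reads(genome, "from_repeats", n_reads=1500,
                                       rng=rng, id_prefix="rep")
        uni_reads, t2 = simulate_reads(genome, "uniform", n_reads=500,
                                       rng=rng, id_prefix="bg")
        reads = rep_reads + uni_reads
        truth = pd.concat([t1, t2], ignore_index=True)
        paths["fastq"] = (out_dir / "reads_100_1.fastq", out_dir / "reads_100_2.fastq")
        write_fastq(reads, paths["fastq"])
        sams: dict[int, Path] = {}
        for L in TRIM_LENGTHS:
            trimmed = [
                (SimRead(m1.name, m1.sequence[:L], m1.quality[:L]),
                 SimRead(m2.name, m2.sequence[:L], m2.quality[:L]))
                for m1, m2 in reads
            ]
            sam = out_dir / f"alignments_{L}.sam"
            exhaustive_align(trimmed, genome, mm, sam,
                             insert_min=50, insert_max=400)
            sams[L] = sam
        paths["sams_by_length"] = sams

    truth.to_csv(paths["truth"], sep="\t", index=False)
    return FixtureBundle(preset=preset, out_dir=out_dir, genome=genome,
                         paths=paths, truth=truth, aligner_max_mismatches=mm)
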