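"""SAM ingestion, read/fragment grouping and classification, and 3' trimming.

A read's mapping multiplicity is the number of alignment records retained
*after* filtering (unmapped records, excluded references, optional MAPQ
threshold) — not the NH tag.  NH, when present, is cross-checked and
discrepancies are counted and logged, since upstream filters legitimately
change the effective multiplicity.  Reads with exactly one surviving mapping
are unimappers; all others are multimappers.  For paired-end data a fragment
is multimapping when it has more than one proper mapping pair.

The loaders buffer records by query name, so an unsorted SAM is handled at the
cost of holding all records of the file in memory at once; name-grouped input
streams with one read's records held at a time.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam

from .core import GenomicInterval, InputError, ParseError

logger = logging.getLogger(__name__)

#: Default kept-reference pattern: primary chromosomes of UCSC-named
#: human/mouse assemblies.  chrM and unplaced/random scaffolds do not match
#: and are therefore excluded (the ChIP-seq filter).
DEFAULT_REFERENCE_PATTERN = r"^chr([0-9]+|X|Y)$"


@dataclass(slots=True)
class FilterConfig:
    """Record-level filters applied before multiplicity is computed.

    ``keep_reference_pattern=None`` keeps all references; the default keeps
    chr1..chrN/chrX/chrY only.  ``min_mapq`` is off by default: the fractional
    strategies are defined on the full mapping set.
    """

    keep_reference_pattern: str | None = DEFAULT_REFERENCE_PATTERN
    min_mapq: int | None = None

    def keeps_reference(self, ref: str) -> bool:
        if self.keep_reference_pattern is None:
            return True
        return re.match(self.keep_reference_pattern, ref) is not None


@dataclass(frozen=True, slots=True)
class Mapping:
    """One alignment of a read: reference span, aligned blocks, read length."""

    interval: GenomicInterval
    aligned_blocks: tuple[tuple[int, int], ...]
    read_length: int

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(slots=True)
class ReadMappingSet:
    """One read with the full list of its retained mappings."""

    read_id: str
    read_length: int
    mappings: list[Mapping]

    @property
    def multiplicity(self) -> int:
        return len(self.mappings)

    @property
    def is_multimapper(self) -> bool:
        return self.multiplicity > 1


@dataclass(slots=True)
class FragmentMappingSet:
    """One proper-paired fragment with its list of mapping pairs."""

    fragment_id: str
    mappings: list[tuple[Mapping, Mapping]]

    @property
    def multiplicity(self) -> int:
        return len(self.mappings)

    @property
    def is_multimapper(self) -> bool:
        return self.multiplicity > 1


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def reference_blocks(cigar: str, pos: int) -> list[tuple[int, int]]:
    """Maximal reference intervals consumed by a CIGAR string starting at ``pos``.

    M/=/X open or extend a block; D is internal to a block (it consumes
    reference); N closes the current block and skips; S/I/H/P consume no
    reference.  Returns 0-based half-open ``(start, end)`` tuples.
    """
    consumed = sum(len(m.group(0)) for m in _CIGAR_RE.finditer(cigar))
    if consumed != len(cigar) or not cigar:
        raise ParseError(f"invalid CIGAR string: {cigar!r}")
    blocks: list[tuple[int, int]] = []
    ref = pos
    block_start: int | None = None
    for m in _CIGAR_RE.finditer(cigar):
        length, op = int(m.group(1)), m.group(2)
        if op in "M=XD":
            if block_start is None:
                block_start = ref
            ref += length
        elif op == "N":
            if block_start is not None:
                blocks.append((block_start, ref))
                block_start = None
            ref += length
        # S, I, H, P: no reference consumed
    if block_start is not None:
        blocks.append((block_start, ref))
    return blocks


def _record_read_length(rec: pysam.AlignedSegment) -> int:
    n = rec.infer_read_length()
    if n:
        return n
    if rec.query_sequence:
        return len(rec.query_sequence)
    return 0


def _mapping_from_record(rec: pysam.AlignedSegment, read_length: int) -> Mapping:
    blocks = tuple(reference_blocks(rec.cigarstring, rec.reference_start))
    return Mapping(
        interval=GenomicInterval(
            rec.reference_name, rec.reference_start, rec.reference_end,
            "-" if rec.is_reverse else "+",
        ),
        aligned_blocks=blocks,
        read_length=read_length,
    )


def _grouped_records(path: str | Path) -> Iterator[tuple[str, list[pysam.AlignedSegment]]]:
    """Yield (query_name, records) groups, buffering the whole file by name."""
    groups: dict[str, list[pysam.AlignedSegment]] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        if not sam.header.to_dict():
            raise ParseError(f"{path}: SAM file has no header")
        for rec in sam:
            name = rec.query_name
            if name not in groups:
                groups[name] = []
                order.append(name)
            groups[name].append(rec)
    for name in order:
        yield name, groups[name]


def load_read_mappings(
    path: str | Path,
    filters: FilterConfig | None = None,
    stats: dict | None = None,
) -> Iterator[ReadMappingSet]:
    """Stream :class:`ReadMappingSet` objects from a SAM file.

    Unmapped records and records on excluded references are dropped *before*
    multiplicity is computed, so a read whose only surviving mapping is on an
    included chromosome counts as a unimapper.  Duplicate identical
    (position, strand, CIGAR) records for a read collapse to one, counted in
    ``stats``.  ``stats``, when supplied, is filled with bookkeeping counters.
    """
    filters = filters if filters is not None else FilterConfig()
    s = stats if stats is not None else {}
    for key in ("records_total", "records_unmapped", "records_filtered_reference",
                "records_filtered_mapq", "records_duplicate", "reads_kept",
                "reads_dropped", "unimappers", "multimappers", "nh_mismatch"):
        s.setdefault(key, 0)

    for name, records in _grouped_records(path):
        kept: list[pysam.AlignedSegment] = []
        seen: set[tuple] = set()
        nh_values: set[int] = set()
        for rec in records:
            s["records_total"] += 1
            if rec.is_unmapped:
                s["records_unmapped"] += 1
                continue
            if not filters.keeps_reference(rec.reference_name):
                s["records_filtered_reference"] += 1
                continue
            if filters.min_mapq is not None and rec.mapping_quality < filters.min_mapq:
                s["records_filtered_mapq"] += 1
                continue
            key = (rec.reference_name, rec.reference_start, rec.is_reverse, rec.cigarstring)
            if key in seen:
                s["records_duplicate"] += 1
                logger.warning("duplicate record collapsed for read %s at %s:%d",
                               name, rec.reference_name, rec.reference_start)
                continue
            seen.add(key)
            if rec.has_tag("NH"):
                nh_values.add(rec.get_tag("NH"))
            kept.append(rec)
        if not kept:
            s["reads_dropped"] += 1
            continue
        read_length = max(_record_read_length(r) for r in kept)
        if read_length == 0:
            raise InputError(f"read {name}: cannot determine read length")
        if nh_values and nh_values != {len(kept)}:
            s["nh_mismatch"] += 1
            logger.debug("read %s: NH tag %s != retained multiplicity %d",
                         name, sorted(nh_values), len(kept))
        s["reads_kept"] += 1
        rs = ReadMappingSet(
            read_id=name,
            read_length=read_length,
            mappings=[_mapping_from_record(r, read_length) for r in kept],
        )
        s["multimappers" if rs.is_multimapper else "unimappers"] += 1
        yield rs


def load_fragment_mappings(
    path: str | Path,
    filters: FilterConfig | None = None,
    stats: dict | None = None,
) -> Iterator[FragmentMappingSet]:
    """Stream proper-paired :class:`FragmentMappingSet` objects from a SAM file.

    Only records with the proper-pair flag survive; mates are joined by
    position/flag concordance (each mate's PNEXT must equal the other's POS on
    the same reference).  Records whose mate cannot be found are dropped and
    counted.  By default no reference filter is applied (the RNA-seq path);
    pass a :class:`FilterConfig` to add one.
    """
    filters = filters if filters is not None else FilterConfig(keep_reference_pattern=None)
    s = stats if stats is not None else {}
    for key in ("records_total", "records_not_proper", "records_filtered_reference",
                "records_mate_missing", "fragments_kept", "fragments_dropped",
                "unimappers", "multimappers"):
        s.setdefault(key, 0)

    for name, records in _grouped_records(path):
        mate1: list[pysam.AlignedSegment] = []
        mate2: list[pysam.AlignedSegment] = []
        for rec in records:
            s["records_total"] += 1
            if rec.is_unmapped or not rec.is_proper_pair:
                s["records_not_proper"] += 1
                continue
            if not filters.keeps_reference(rec.reference_name):
                s["records_filtered_reference"] += 1
                continue
            (mate1 if rec.is_read1 else mate2).append(rec)

        pairs: list[tuple[pysam.AlignedSegment, pysam.AlignedSegment]] = []
        used = [False] * len(mate2)
        for r1 in mate1:
            found = False
            for j, r2 in enumerate(mate2):
                if used[j]:
                    continue
                if (r2.reference_name == r1.reference_name
                        and r2.reference_start == r1.next_reference_start
                        and r1.reference_start == r2.next_reference_start):
                    pairs.append((r1, r2))
                    used[j] = True
                    found = True
                    break
            if not found:
                s["records_mate_missing"] += 1
                logger.warning("proper-pair record without joinable mate: %s", name)
        s["records_mate_missing"] += used.count(False)

        if not pairs:
            s["fragments_dropped"] += 1
            continue
        mappings = []
        for r1, r2 in pairs:
            l1 = _record_read_length(r1)
            l2 = _record_read_length(r2)
            mappings.append((_mapping_from_record(r1, l1), _mapping_from_record(r2, l2)))
        s["fragments_kept"] += 1
        fs = FragmentMappingSet(fragment_id=name, mappings=mappings)
        s["multimappers" if fs.is_multimapper else "unimappers"] += 1
        yield fs


def random_select(
    rs: ReadMappingSet | FragmentMappingSet,
    rng: np.random.Generator,
) -> ReadMappingSet | FragmentMappingSet:
    """Reduce a mapping set to a single uniformly chosen mapping.

    Unimappers are returned unchanged (and consume no randomness), so a fixed
    seed and input order give a deterministic result.
    """
    if rs.multiplicity == 1:
        return rs
    idx = int(rng.integers(rs.multiplicity))
    if isinstance(rs, ReadMappingSet):
        return ReadMappingSet(rs.read_id, rs.read_length, [rs.mappings[idx]])
    return FragmentMappingSet(rs.fragment_id, [rs.mappings[idx]])


def _open_text(path: str | Path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def _trim_one(in_path: str | Path, out_path: str | Path, target_length: int) -> int:
    n = 0
    with pysam.FastxFile(str(in_path)) as fh, _open_text(out_path, "w") as out:
        records = iter(fh)
        while True:
            try:
                rec = next(records)
            except StopIteration:
                break
            except ValueError as exc:  # pysam: malformed record (e.g. short qual)
                raise InputError(f"{in_path}, record {n + 1}: {exc}") from exc
            if rec.quality is not None and len(rec.quality) != len(rec.sequence):
                raise InputError(
                    f"record {rec.name}: sequence/quality length mismatch "
                    f"({len(rec.sequence)} vs {len(rec.quality)})"
                )
            seq = rec.sequence[:target_length]
            qual = rec.quality[:target_length] if rec.quality is not None else "I" * len(seq)
            comment = f" {rec.comment}" if rec.comment else ""
            out.write(f"@{rec.name}{comment}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def trim_reads_3prime(
    paths: str | Path | tuple,
    target_length: int,
    out_paths: str | Path | tuple,
) -> int:
    """Truncate reads to ``target_length`` keeping the 5' end.

    Accepts a single FASTQ or a (mate1, mate2) pair; IDs and pairing are
    preserved, and reads already at or below the target length pass through
    unchanged.  Returns the number of records written (per file for pairs).
    """
    if target_length < 1:
        raise InputError(f"target_length must be >= 1, got {target_length}")
    if isinstance(paths, (tuple, list)):
        if not isinstance(out_paths, (tuple, list)) or len(paths) != len(out_paths):
            raise InputError("paired input requires matching paired output paths")
        counts = [_trim_one(p, o, target_length) for p, o in zip(paths, out_paths)]
        if len(set(counts)) != 1:
            raise InputError(f"mate files have different record counts: {counts}")
        return counts[0]
    return _trim_one(paths, out_paths, target_length)


def write_random_selection(
    in_sam: str | Path,
    out_sam: str | Path,
    seed: int,
    paired: bool = False,
) -> dict:
    """Re-emit a SAM keeping one uniformly chosen mapping per read (or one
    proper pair per fragment), with secondary flags cleared and NH reset to 1.

    Unimappers pass through unchanged and consume no randomness, so output is
    deterministic under a fixed seed and input order.  Returns counters.
    """
    rng = np.random.default_rng(seed)
    stats = {"reads": 0, "selected_from_multi": 0, "records_out": 0}
    with pysam.AlignmentFile(str(in_sam), "r", check_sq=False) as sam_in:
        header = sam_in.header
        groups: dict[str, list[pysam.AlignedSegment]] = {}
        order: list[str] = []
        for rec in sam_in:
            if rec.query_name not in groups:
                groups[rec.query_name] = []
                order.append(rec.query_name)
            groups[rec.query_name].append(rec)
    with pysam.AlignmentFile(str(out_sam), "wh", header=header) as out:
        for name in order:
            records = groups[name]
            if paired:
                units = _pair_units(records)
            else:
                units = [[r] for r in records if not r.is_unmapped]
            if not units:
                continue
            stats["reads"] += 1
            if len(units) == 1:
                chosen = units[0]
            else:
                chosen = units[int(rng.integers(len(units)))]
                stats["selected_from_multi"] += 1
            for rec in chosen:
                rec.is_secondary = False
                if rec.has_tag("NH"):
                    rec.set_tag("NH", 1)
                out.write(rec)
                stats["records_out"] += 1
    return stats


def _pair_units(records: list[pysam.AlignedSegment]) -> list[list[pysam.AlignedSegment]]:
    mate1 = [r for r in records if not r.is_unmapped and r.is_proper_pair and r.is_read1]
    mate2 = [r for r in records if not r.is_unmapped and r.is_proper_pair and r.is_read2]
    units: list[list[pysam.AlignedSegment]] = []
    used = [False] * len(mate2)
    for r1 in mate1:
        for j, r2 in enumerate(mate2):
            if used[j]:
                continue
            if (r2.reference_name == r1.reference_name
                    and r2.reference_start == r1.next_reference_start
                    and r1.reference_start == r2.next_reference_start):
                units.append([r1, r2])
                used[j] = True
                break
    return units


def classify_counts(sets: Iterable[ReadMappingSet | FragmentMappingSet]) -> dict:
    """Count unimappers/multimappers in a stream; returns a summary dict."""
    uni = multi = 0
    for rs in sets:
        if rs.is_multimapper:
            multi += 1
        else:
            uni += 1
    total = uni + multi
    return {
        "total": total,
        "unimappers": uni,
        "multimappers": multi,
        "multimapper_fraction": (multi / total) if total else float("nan"),
    }
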