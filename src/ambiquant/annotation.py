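"""Repeat and gene annotation handling.

Repeat annotations (UCSC RepeatMasker table export or BED6) are parsed into
:class:`~ambiquant.core.RepeatCopy` records; copies sharing a repeat name are
merged when they overlap or are immediately adjacent (zero gap in half-open
coordinates) and collected into TE groups.  Each group can be assigned the
youngest of the clades listed for its name in a Dfam-style table.  Gene models
come from a GENCODE-dialect GTF; a gene's length is its genomic span while
overlap later uses its exon union.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable

import gffutils

from .core import (
    CladeTable,
    ConfigurationError,
    GeneModel,
    GenomicInterval,
    ParseError,
    RepeatCopy,
    TEGroup,
)

logger = logging.getLogger(__name__)

_RMSK_COLUMNS = ("genoName", "genoStart", "genoEnd", "strand", "repName",
                 "repClass", "repFamily")


def parse_repeat_annotation(path: str | Path, dialect: str = "bed6") -> list[RepeatCopy]:
    """Parse a repeat annotation file into sorted :class:`RepeatCopy` records.

    Parameters
    ----------
    path:
        Input file.
    dialect:
        ``"bed6"`` (columns chrom/start/end/name[/score[/strand]]) or
        ``"rmsk-tsv"`` (UCSC RepeatMasker table export with a header naming at
        least genoName/genoStart/genoEnd/repName).

    Returns copies sorted by (chrom, start, end).
    """
    if dialect == "bed6":
        copies = _parse_bed6(Path(path))
    elif dialect == "rmsk-tsv":
        copies = _parse_rmsk(Path(path))
    else:
        raise ConfigurationError(f"unknown repeat annotation dialect: {dialect!r}")
    copies.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    return copies


def _parse_bed6(path: Path) -> list[RepeatCopy]:
    copies: list[RepeatCopy] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >=4 BED columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
                strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
                copies.append(RepeatCopy(
                    name=fields[3],
                    interval=GenomicInterval(fields[0], start, end, strand),
                ))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return copies


def _parse_rmsk(path: Path) -> list[RepeatCopy]:
    copies: list[RepeatCopy] = []
    with open(path) as fh:
        header_line = fh.readline()
        header = header_line.lstrip("#").rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        missing = [c for c in ("genoName", "genoStart", "genoEnd", "repName") if c not in idx]
        if missing:
            raise ParseError(f"{path}:1: rmsk header missing columns {missing}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                strand = fields[idx["strand"]] if "strand" in idx else "."
                if strand not in "+-":
                    strand = "."
                copies.append(RepeatCopy(
                    name=fields[idx["repName"]],
                    interval=GenomicInterval(
                        fields[idx["genoName"]],
                        int(fields[idx["genoStart"]]),
                        int(fields[idx["genoEnd"]]),
                        strand,
                    ),
                    repeat_class=fields[idx["repClass"]] if "repClass" in idx else "Other",
                    repeat_family=fields[idx["repFamily"]] if "repFamily" in idx else "Other",
                ))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return copies


def merge_same_name(copies: Iterable[RepeatCopy]) -> list[TEGroup]:
    """Merge overlapping or immediately adjacent same-name copies into groups.

    Within each repeat name and chromosome, intervals that overlap or touch
    (``end_i == start_j`` in half-open coordinates) collapse into one copy
    spanning their union.  A 1-bp gap is *not* merged.  Copies with different
    names never merge, regardless of overlap.  Strand is ignored for merging;
    a merged copy keeps the strand of its first contributing interval.
    """
    by_name: dict[str, list[RepeatCopy]] = defaultdict(list)
    for c in copies:
        by_name[c.name].append(c)

    groups: list[TEGroup] = []
    for name in sorted(by_name):
        merged: list[RepeatCopy] = []
        group_copies = sorted(
            by_name[name], key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end)
        )
        cur: RepeatCopy | None = None
        for c in group_copies:
            if (
                cur is not None
                and c.interval.chrom == cur.interval.chrom
                and c.interval.start <= cur.interval.end
            ):
                if c.interval.end > cur.interval.end:
                    cur = RepeatCopy(
                        name=name,
                        interval=GenomicInterval(
                            cur.interval.chrom, cur.interval.start,
                            c.interval.end, cur.interval.strand,
                        ),
                        repeat_class=cur.repeat_class,
                        repeat_family=cur.repeat_family,
                    )
            else:
                if cur is not None:
                    merged.append(cur)
                cur = c
        if cur is not None:
            merged.append(cur)
        groups.append(TEGroup(name=name, copies=merged))
    return groups


def assign_clade(group: TEGroup, clades: CladeTable) -> str | None:
    """Return the youngest clade listed for the group's name, or ``None``.

    Names absent from the table (or listed with no clades) return ``None`` and
    are excluded from clade-level aggregation downstream.  A clade label that
    is present in the table but missing from the ordering raises
    :class:`ConfigurationError`.
    """
    labels = clades.entries.get(group.name)
    if not labels:
        return None
    return min(labels, key=clades.rank)


def assign_clades(groups: Iterable[TEGroup], clades: CladeTable) -> None:
    """Set ``group.clade`` in place for every group."""
    for g in groups:
        g.clade = assign_clade(g, clades)


def read_clade_table(entries_path: str | Path,
                     ordering: str | Path | list[str] | None = None) -> CladeTable:
    """Load a clade table from a TSV (columns ``name``, ``clades``) plus an
    ordering given as a list or a one-label-per-line file.  ``None`` uses the
    default human-lineage ordering."""
    from .core import DEFAULT_CLADE_ORDERING

    entries: dict[str, set[str]] = {}
    with open(entries_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or (lineno == 1 and line.startswith("name\t")):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{entries_path}:{lineno}: expected name<TAB>clades")
            labels = {c.strip() for c in fields[1].split(",") if c.strip()}
            entries.setdefault(fields[0], set()).update(labels)
    if ordering is None:
        order = list(DEFAULT_CLADE_ORDERING)
    elif isinstance(ordering, (str, Path)):
        with open(ordering) as fh:
            order = [ln.strip() for ln in fh if ln.strip()]
    else:
        order = list(ordering)
    return CladeTable(entries=entries, ordering=order)


def parse_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse a GENCODE-dialect GTF into :class:`GeneModel` records.

    Gene length is the genomic span (end - start after conversion to 0-based
    half-open), not the exon sum.  Exons whose ``gene_id`` has no gene feature
    get a gene span synthesized from their extremes, with a logged warning.
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    genes: dict[str, GeneModel] = {}
    exons_by_gene: dict[str, list[GenomicInterval]] = defaultdict(list)
    chrom_by_gene: dict[str, str] = {}

    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes["gene_id"][0]
        biotype = "unknown"
        for key in ("gene_type", "gene_biotype"):
            if key in feat.attributes:
                biotype = feat.attributes[key][0]
                break
        genes[gene_id] = GeneModel(
            gene_id=gene_id,
            span=GenomicInterval(feat.seqid, feat.start - 1, feat.end,
                                 feat.strand if feat.strand in "+-" else "."),
            biotype=biotype,
        )
    for feat in db.features_of_type("exon"):
        gene_id = feat.attributes["gene_id"][0]
        exons_by_gene[gene_id].append(
            GenomicInterval(feat.seqid, feat.start - 1, feat.end,
                            feat.strand if feat.strand in "+-" else ".")
        )
        chrom_by_gene[gene_id] = feat.seqid

    for gene_id, exons in exons_by_gene.items():
        exons.sort(key=lambda e: (e.start, e.end))
        if gene_id not in genes:
            logger.warning(
                "gene_id %s has exon features but no gene feature; "
                "synthesizing span from exon extremes", gene_id,
            )
            genes[gene_id] = GeneModel(
                gene_id=gene_id,
                span=GenomicInterval(chrom_by_gene[gene_id],
                                     min(e.start for e in exons),
                                     max(e.end for e in exons)),
            )
        genes[gene_id].exons = exons
    return [genes[g] for g in sorted(genes)]


def write_groups_bed(groups: Iterable[TEGroup], path: str | Path) -> None:
    """Write merged group copies as BED6 (score column 0)."""
    rows = []
    for g in groups:
        for c in g.copies:
            rows.append((c.interval.chrom, c.interval.start, c.interval.end,
                         g.name, 0, c.interval.strand if c.interval.strand in "+-" else "+"))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


def write_group_summary(groups: Iterable[TEGroup], path: str | Path) -> None:
    """Write a per-group TSV: name, n_copies, total_bp, clade ('.' if absent)."""
    with open(path, "w") as fh:
        fh.write("name\tn_copies\ttotal_bp\tclade\n")
        for g in sorted(groups, key=lambda g: g.name):
            fh.write(f"{g.name}\t{g.n_copies}\t{g.total_bp}\t{g.clade or '.'}\n")
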