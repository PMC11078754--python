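"""Shared fixtures: synthetic preset bundles and micro SAM/GTF builders."""

from __future__ import annotations

from pathlib import Path

import pytest

from ambiquant.synthetic import make_fixture

FIXTURE_SEED = 7

SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:1000000\n"


def sam_line(name, flag, chrom, pos0, cigar, rnext="*", pnext0=-1, tlen=0,
             seq="*", qual="*", tags=()):
    """One SAM record line; positions are 0-based and converted to 1-based."""
    fields = [name, str(flag), chrom, str(pos0 + 1), "30", cigar, rnext,
              str(pnext0 + 1), str(tlen), seq, qual]
    fields += list(tags)
    return "\t".join(fields) + "\n"


def single_end_records(name, mappings, chrom="chr1"):
    """SAM lines for one single-end read with ``mappings`` = [(pos, cigar), ...]."""
    lines = []
    for i, (pos, cigar) in enumerate(mappings):
        flag = 0 if i == 0 else 256
        lines.append(sam_line(name, flag, chrom, pos, cigar))
    return lines


def paired_records(name, pair_mappings, chrom="chr1", read_len=50):
    """SAM lines for one fragment; ``pair_mappings`` = [(pos1, pos2), ...].

    Both mates get ``read_len``M CIGARs, FR orientation, proper-pair flags.
    """
    lines = []
    for i, (p1, p2) in enumerate(pair_mappings):
        sec = 0 if i == 0 else 256
        tlen = (p2 + read_len) - p1
        lines.append(sam_line(name, 99 | sec, chrom, p1, f"{read_len}M",
                              "=", p2, tlen))
        lines.append(sam_line(name, 147 | sec, chrom, p2, f"{read_len}M",
                              "=", p1, -tlen))
    return lines


def write_sam(path: Path, lines, header: str = SAM_HEADER) -> Path:
    path.write_text(header + "".join(lines))
    return path


def write_gtf(path: Path, genes) -> Path:
    """``genes`` = [(gene_id, biotype, span0, [exon0, ...]), ...] with 0-based
    half-open (start, end) tuples; written as 1-based GTF."""
    lines = []
    for gene_id, biotype, (gs, ge), exons in genes:
        attrs = f'gene_id "{gene_id}"; gene_type "{biotype}";'
        lines.append(f"chr1\ttest\tgene\t{gs + 1}\t{ge}\t.\t+\t.\t{attrs}\n")
        for es, ee in exons:
            lines.append(
                f"chr1\ttest\texon\t{es + 1}\t{ee}\t.\t+\t.\t{attrs} "
                f'transcript_id "{gene_id}.t1";\n')
    path.write_text("".join(lines))
    return path


@pytest.fixture(scope="session")
def young_old_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("young_vs_old_te")
    return make_fixture("young_vs_old_te", out, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def paralog_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("paralog_genes")
    return make_fixture("paralog_genes", out, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def trim_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("trim_series")
    return make_fixture("trim_series", out, seed=FIXTURE_SEED)
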