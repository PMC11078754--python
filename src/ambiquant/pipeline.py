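"""Staged, reproducible runs tying annotation, alignment and counting together.

Every run writes its resolved configuration next to its outputs and logs the
per-stage bookkeeping counts (records loaded, filtered, classified).  Outputs
are plain TSVs with a fixed header line and '.' for undefined values so
downstream R/statistics tools ingest them directly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation, gene_quant, te_coverage
from .alignment import FilterConfig, load_fragment_mappings, load_read_mappings
from .core import AmbiquantError, InputError
from .gene_quant import FragmentAssignments

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class RunConfig:
    """Configuration of one pipeline run.

    ``kind`` selects the stage chain: ``te-coverage`` (repeat annotation +
    single-end SAM -> coverage and clade tables) or ``gene-count`` (GTF +
    paired SAM -> count table under all three strategies plus a comparison).
    """

    kind: str
    out_dir: str
    sam: str
    repeats: str | None = None
    repeat_dialect: str = "bed6"
    clades: str | None = None
    clade_ordering: str | None = None
    gtf: str | None = None
    reference_pattern: str | None = None  # None -> keep all references
    min_mapq: int | None = None
    seed: int = 0
    under_quantified_factor: float = 2.0
    multimapper_threshold: float = 0.70
    top_n: tuple[int, ...] = (50, 100, 200)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "top_n" in data:
            data["top_n"] = tuple(data["top_n"])
        return cls(**data)


def _echo_config(config: RunConfig, out_dir: Path) -> None:
    data = dataclasses.asdict(config)
    data["top_n"] = list(data["top_n"])
    with open(out_dir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stage chain; returns a result summary dict."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("sam", "repeats", "clades", "gtf"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            raise InputError(f"missing input file for {name!r}: {path}")
    _echo_config(config, out_dir)
    if config.kind == "te-coverage":
        return _run_te_coverage(config, out_dir)
    if config.kind == "gene-count":
        return _run_gene_count(config, out_dir)
    raise InputError(f"unknown pipeline kind: {config.kind!r}")


def _run_te_coverage(config: RunConfig, out_dir: Path) -> dict:
    if config.repeats is None:
        raise InputError("te-coverage run requires a repeat annotation")
    copies = annotation.parse_repeat_annotation(config.repeats, config.repeat_dialect)
    groups = annotation.merge_same_name(copies)
    logger.info("annotation: %d copies -> %d groups", len(copies), len(groups))
    ordering = None
    if config.clades is not None:
        table = annotation.read_clade_table(config.clades, config.clade_ordering)
        annotation.assign_clades(groups, table)
        ordering = table.ordering

    filters = FilterConfig(keep_reference_pattern=config.reference_pattern,
                           min_mapq=config.min_mapq)
    stats: dict = {}
    reads = list(load_read_mappings(config.sam, filters, stats))
    logger.info("alignment: %(reads_kept)d reads kept "
                "(%(unimappers)d uni / %(multimappers)d multi), "
                "%(reads_dropped)d dropped", stats)

    cov = te_coverage.te_group_coverage(reads, groups, class_filter="all")
    frac, frac_summary = te_coverage.multimapper_fraction_per_group(
        reads, groups, config.multimapper_threshold)
    cov.to_csv(out_dir / "te_coverage.tsv", sep="\t", index=False,
               na_rep=".", float_format="%.6g")
    frac.to_csv(out_dir / "te_multimapper_fraction.tsv", sep="\t", index=False,
                na_rep=".", float_format="%.6g")
    annotation.write_groups_bed(groups, out_dir / "merged_repeats.bed")
    annotation.write_group_summary(groups, out_dir / "group_summary.tsv")
    if ordering is not None:
        clade = te_coverage.aggregate_by_clade(cov, groups, ordering)
        clade.to_csv(out_dir / "clade_coverage.tsv", sep="\t", index=False,
                     na_rep=".", float_format="%.6g")
    return {"stats": stats, "n_groups": len(groups),
            "multimapper_group_summary": frac_summary,
            "coverage": cov, "out_dir": str(out_dir)}


def _run_gene_count(config: RunConfig, out_dir: Path) -> dict:
    if config.gtf is None:
        raise InputError("gene-count run requires a GTF")
    genes = annotation.parse_gene_models(config.gtf)
    filters = FilterConfig(keep_reference_pattern=config.reference_pattern,
                           min_mapq=config.min_mapq)
    stats: dict = {}
    fragments = list(load_fragment_mappings(config.sam, filters, stats))
    logger.info("alignment: %(fragments_kept)d fragments kept "
                "(%(unimappers)d uni / %(multimappers)d multi), "
                "%(fragments_dropped)d dropped", stats)

    assignments = FragmentAssignments(fragments, genes)
    H = assignments.unique_counts()
    C = assignments.fractional_counts()
    import numpy as np

    R = assignments.random_counts(np.random.default_rng(config.seed))
    table = gene_quant.expression_and_flags(genes, H, C, R,
                                            factor=config.under_quantified_factor)
    gene_quant.write_gene_counts(table, out_dir / "gene_counts.tsv")

    top_rows = []
    for n in config.top_n:
        for which in ("expr_H", "expr_C"):
            top = gene_quant.top_n_protein_coding(table, n, which)
            for rank, gid in enumerate(top["gene_id"], start=1):
                top_rows.append({"n": n, "ranking": which, "rank": rank,
                                 "gene_id": gid})
    pd.DataFrame(top_rows).to_csv(out_dir / "top_genes.tsv", sep="\t", index=False)
    return {"stats": stats, "table": table, "out_dir": str(out_dir)}


def compare_strategies_report(
    tables: dict[str, pd.DataFrame],
    factor: float = 2.0,
    top_n: tuple[int, ...] = (50, 100, 200),
) -> tuple[pd.DataFrame, dict]:
    """Side-by-side comparison of gene count tables from >= 2 strategies.

    All tables must share the same gene universe; mismatches raise with the
    offending ids.  Returns the merged per-gene table and a summary with the
    under-quantified share among expressed genes and top-N set symmetric
    differences between the first two strategies.
    """
    if len(tables) < 2:
        raise InputError("need at least two strategy tables to compare")
    names = list(tables)
    universe = set(tables[names[0]]["gene_id"])
    for name in names[1:]:
        other = set(tables[name]["gene_id"])
        if other != universe:
            offending = sorted(universe.symmetric_difference(other))
            raise InputError(
                f"gene universes differ between {names[0]!r} and {name!r}: "
                f"{offending[:20]}")

    merged = tables[names[0]][["gene_id", "biotype", "length"]].copy()
    for name in names:
        t = tables[name].set_index("gene_id")
        for col in ("H", "C", "expr_H", "expr_C"):
            if col in t.columns:
                merged[f"{col}_{name}"] = merged["gene_id"].map(t[col])

    ref = tables[names[0]].set_index("gene_id")
    expressed = ref["expressed"]
    under = ref["under_quantified"]
    n_expressed = int(expressed.sum())
    summary = {
        "strategies": names,
        "n_genes": len(universe),
        "n_expressed": n_expressed,
        "n_under_quantified": int((under & expressed).sum()),
        "under_quantified_share_among_expressed":
            (int((under & expressed).sum()) / n_expressed) if n_expressed else float("nan"),
        "top_n_symmetric_difference": {},
    }
    a, b = tables[names[0]], tables[names[1]]
    for n in top_n:
        top_a = set(gene_quant.top_n_protein_coding(a, n, "expr_H")["gene_id"])
        top_b = set(gene_quant.top_n_protein_coding(b, n, "expr_C")["gene_id"])
        summary["top_n_symmetric_difference"][n] = len(top_a ^ top_b)
    return merged, summary
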