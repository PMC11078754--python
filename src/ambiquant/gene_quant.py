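"""Gene quantification under three multimapper-handling strategies.

All three share union-mode gene assignment: a mapping pair's gene set S is
every gene with at least one exon overlapped (>= 1 base) by an aligned block
of either mate.  A mapping counts to a gene only when S is a singleton —
|S| = 0 (no feature) and |S| >= 2 (ambiguous) count to nothing.

* unique-only baseline H_g: only fragments with a single mapping contribute,
  replicating HTSeq-count union mode with ``--nonunique none``;
* fractional C_g: every mapping f_i of fragment f contributes
  I_g(f_i) / |M_f|, so a fragment spreads at most one unit of count over the
  genes its mappings unambiguously hit;
* random selection R_g: one mapping chosen uniformly per fragment, then the
  unique-only assignment rule applied to it.  E[R_g] = C_g.

Expression values divide counts by the gene's genomic span length L_g.  A gene
is "expressed" when C_g > 0 and "under-quantified" when
(C_g/L_g)/(H_g/L_g) > factor (default 2, strict); H_g = 0 with C_g > 0 is
treated as an infinite ratio, hence under-quantified.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .alignment import FragmentMappingSet, Mapping
from .core import GeneModel, InputError

logger = logging.getLogger(__name__)


def build_exon_index(genes: Iterable[GeneModel]) -> dict[str, IntervalTree]:
    """Per-chromosome interval tree over exons, carrying gene ids."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        for e in g.exons:
            trees[e.chrom].addi(e.start, e.end, g.gene_id)
    return dict(trees)


def overlapping_genes(
    pair_mapping: tuple[Mapping, Mapping] | Mapping,
    exon_index: dict[str, IntervalTree],
) -> set[str]:
    """The gene set S of a mapping (pair): union-mode exon overlap over mates."""
    mates = pair_mapping if isinstance(pair_mapping, tuple) else (pair_mapping,)
    s: set[str] = set()
    for m in mates:
        tree = exon_index.get(m.chrom)
        if tree is None:
            continue
        for bs, be in m.aligned_blocks:
            for iv in tree.overlap(bs, be):
                s.add(iv.data)
    return s


@dataclass(slots=True)
class _AssignedFragment:
    fragment_id: str
    multiplicity: int
    # per mapping: the assigned gene id when |S| == 1, else None
    assigned: list[str | None]


class FragmentAssignments:
    """Pre-resolved gene assignments for a fragment collection.

    Resolving S per mapping once lets the unique-only, fractional and random
    strategies (and repeated random draws) run off the same assignment table.
    """

    def __init__(self, fragments: Iterable[FragmentMappingSet],
                 genes: Sequence[GeneModel]):
        self.gene_ids = [g.gene_id for g in genes]
        index = build_exon_index(genes)
        self.fragments: list[_AssignedFragment] = []
        for f in fragments:
            assigned = []
            for pair in f.mappings:
                s = overlapping_genes(pair, index)
                assigned.append(next(iter(s)) if len(s) == 1 else None)
            self.fragments.append(
                _AssignedFragment(f.fragment_id, len(f.mappings), assigned))

    def _as_series(self, acc: dict[str, float]) -> pd.Series:
        s = pd.Series(0.0, index=pd.Index(self.gene_ids, name="gene_id"))
        for gene, v in acc.items():
            s[gene] = v
        return s

    def unique_counts(self) -> pd.Series:
        """H_g: unimapper fragments with a singleton gene set only."""
        acc: dict[str, float] = defaultdict(float)
        for f in self.fragments:
            if f.multiplicity == 1 and f.assigned[0] is not None:
                acc[f.assigned[0]] += 1
        return self._as_series(acc)

    def fractional_counts(self) -> pd.Series:
        """C_g: every unambiguous mapping contributes 1/|M_f|."""
        acc: dict[str, float] = defaultdict(float)
        for f in self.fragments:
            w = 1.0 / f.multiplicity
            for gene in f.assigned:
                if gene is not None:
                    acc[gene] += w
        return self._as_series(acc)

    def random_counts(self, rng: np.random.Generator) -> pd.Series:
        """R_g: one uniformly chosen mapping per fragment, then the unique rule.

        Unimappers consume no randomness, mirroring
        :func:`ambiquant.alignment.random_select`.
        """
        acc: dict[str, float] = defaultdict(float)
        for f in self.fragments:
            idx = 0 if f.multiplicity == 1 else int(rng.integers(f.multiplicity))
            gene = f.assigned[idx]
            if gene is not None:
                acc[gene] += 1
        return self._as_series(acc)


def count_unique_only(fragments: Iterable[FragmentMappingSet],
                      genes: Sequence[GeneModel]) -> pd.Series:
    """Unique-only counts H_g (HTSeq-count ``--nonunique none`` semantics)."""
    return FragmentAssignments(fragments, genes).unique_counts()


def count_multimapper_aware(fragments: Iterable[FragmentMappingSet],
                            genes: Sequence[GeneModel]) -> pd.Series:
    """Fractional multimapper-aware counts C_g."""
    return FragmentAssignments(fragments, genes).fractional_counts()


def count_random_strategy(fragments: Iterable[FragmentMappingSet],
                          genes: Sequence[GeneModel],
                          seed: int) -> pd.Series:
    """Random-selection counts R_g under a fixed seed."""
    rng = np.random.default_rng(seed)
    return FragmentAssignments(fragments, genes).random_counts(rng)


def expression_and_flags(
    genes: Sequence[GeneModel],
    H: pd.Series,
    C: pd.Series,
    R: pd.Series | None = None,
    factor: float = 2.0,
) -> pd.DataFrame:
    """Assemble the per-gene count table with expression values and flags.

    ``under_quantified`` uses the strict ratio (C/L)/(H/L) > factor, which
    reduces to C/H > factor; H = 0 with C > 0 is an infinite ratio (flagged),
    H = C = 0 is not flagged.  ``expressed`` is C > 0.
    """
    rows = []
    for g in genes:
        h = float(H.get(g.gene_id, 0.0))
        c = float(C.get(g.gene_id, 0.0))
        if h < 0 or c < 0:
            raise InputError(f"negative count for gene {g.gene_id}")
        if h > 0:
            under = (c / h) > factor
        else:
            under = c > 0
        rows.append({
            "gene_id": g.gene_id,
            "biotype": g.biotype,
            "length": g.length,
            "H": h,
            "C": c,
            "C_rounded": math.floor(c + 0.5),
            "R": float(R.get(g.gene_id, 0.0)) if R is not None else float("nan"),
            "expr_H": h / g.length,
            "expr_C": c / g.length,
            "expressed": c > 0,
            "under_quantified": under,
        })
    return pd.DataFrame(rows)


def top_n_protein_coding(table: pd.DataFrame, n: int,
                         which: str = "expr_C") -> pd.DataFrame:
    """Top-n protein-coding genes ranked by an expression column.

    Sorts descending with a deterministic tie-break by ascending gene_id.
    Warns (and returns everything available) when fewer than ``n``
    protein-coding genes are expressed.
    """
    if which not in ("expr_H", "expr_C"):
        raise InputError(f"which must be expr_H or expr_C, got {which!r}")
    pc = table[table["biotype"] == "protein_coding"]
    if int((pc[which] > 0).sum()) < n:
        logger.warning("only %d protein-coding genes with %s > 0 (requested %d)",
                       int((pc[which] > 0).sum()), which, n)
    ranked = pc.sort_values(by=[which, "gene_id"],
                            ascending=[False, True], kind="mergesort")
    return ranked.head(n)


def write_gene_counts(table: pd.DataFrame, path: str | Path) -> None:
    """Write the gene count table as TSV ('.' for undefined values)."""
    out = table.copy()
    out.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.6g")
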