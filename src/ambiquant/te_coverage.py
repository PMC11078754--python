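"""Fractional, overlap-weighted read coverage per TE group.

For a TE group K (the merged copies sharing one repeat name) the coverage is

    C_K = sum_{k in K} sum_{r in Q} sum_{r_i in M_r} [ I_k(r_i) / |M_r| ] * ( l_{k,r_i} / L_r )

where M_r is the set of loci read r maps to, l_{k,r_i} is the number of
aligned bases of mapping r_i overlapping copy k, and L_r is the read length in
bases (soft-clipped bases included).  Each mapping therefore contributes its
overlap fraction, down-weighted by the read's mapping multiplicity.  Overlap
is evaluated on the aligned reference blocks, so N-gapped (spliced) segments
do not count intronic span.

Coverage is stratified by read class (unimapper / multimapper / all), and can
be aggregated per age clade once groups carry clade labels.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .alignment import Mapping, ReadMappingSet
from .core import InputError, RepeatCopy, TEGroup

CLASSES = ("unimapper", "multimapper", "all")


def overlap_length(mapping: Mapping, copy: RepeatCopy) -> int:
    """Aligned bases of ``mapping`` overlapping the copy's interval (l_{k,r_i})."""
    if mapping.chrom != copy.interval.chrom:
        return 0
    total = 0
    for bs, be in mapping.aligned_blocks:
        total += max(0, min(be, copy.interval.end) - max(bs, copy.interval.start))
    return total


def build_copy_index(groups: Iterable[TEGroup]) -> dict[str, IntervalTree]:
    """Per-chromosome interval tree of (group name, copy) over merged copies."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in groups:
        for c in g.copies:
            trees[c.interval.chrom].addi(c.interval.start, c.interval.end, (g.name, c))
    return dict(trees)


def _read_terms(read: ReadMappingSet,
                index: dict[str, IntervalTree]) -> dict[str, list[float]]:
    """Per-group list of coverage terms [I_k(r_i)/|M_r|] * (l/L_r) of one read."""
    if read.read_length <= 0:
        raise InputError(f"read {read.read_id}: non-positive read length")
    terms: dict[str, list[float]] = defaultdict(list)
    for m in read.mappings:
        tree = index.get(m.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(m.start, m.end):
            group_name, copy = iv.data
            l = overlap_length(m, copy)
            if l > 0:
                terms[group_name].append((l / read.read_length) / read.multiplicity)
    return terms


def _read_contributions(read: ReadMappingSet,
                        index: dict[str, IntervalTree]) -> dict[str, float]:
    """Per-group coverage contribution of one read (summed over its mappings)."""
    return {name: math.fsum(ts) for name, ts in _read_terms(read, index).items()}


def te_group_coverage(
    reads: Iterable[ReadMappingSet],
    groups: Sequence[TEGroup],
    class_filter: str = "all",
) -> pd.DataFrame:
    """Compute the coverage table, one row per TE group and read class.

    ``class_filter`` of ``"all"`` emits unimapper, multimapper and combined
    rows; ``"unimapper"``/``"multimapper"`` restrict to that stratum.  Groups
    touched by no read appear with coverage 0 and an undefined (NaN)
    multimapper read fraction.  The combined coverage equals the unimapper
    plus multimapper coverage by construction.
    """
    if class_filter not in CLASSES:
        raise InputError(f"class_filter must be one of {CLASSES}, got {class_filter!r}")
    index = build_copy_index(groups)
    # term-level accumulation summed with fsum: the result is the correctly
    # rounded value of the defining triple sum, independent of read order
    terms: dict[str, dict[str, list[float]]] = {
        g.name: {"unimapper": [], "multimapper": []} for g in groups}
    touch = {name: {"unimapper": 0, "multimapper": 0} for name in terms}

    for read in reads:
        cls = "multimapper" if read.is_multimapper else "unimapper"
        for group_name, ts in _read_terms(read, index).items():
            terms[group_name][cls].extend(ts)
            touch[group_name][cls] += 1
    cov = {name: {cls: math.fsum(ts) for cls, ts in by_cls.items()}
           for name, by_cls in terms.items()}

    clade_of = {g.name: g.clade for g in groups}
    rows = []
    emit = CLASSES if class_filter == "all" else (class_filter,)
    for g in groups:
        name = g.name
        n_uni, n_multi = touch[name]["unimapper"], touch[name]["multimapper"]
        n_touch = n_uni + n_multi
        mm_frac = (n_multi / n_touch) if n_touch else float("nan")
        for cls in emit:
            if cls == "all":
                coverage = math.fsum(terms[name]["unimapper"]
                                     + terms[name]["multimapper"])
                n = n_touch
            else:
                coverage = cov[name][cls]
                n = touch[name][cls]
            rows.append({
                "group": name,
                "clade": clade_of[name],
                "class": cls,
                "coverage": coverage,
                "n_reads_touching": n,
                "multimapper_read_fraction": mm_frac,
            })
    return pd.DataFrame(rows)


def multimapper_fraction_per_group(
    reads: Iterable[ReadMappingSet],
    groups: Sequence[TEGroup],
    threshold: float = 0.70,
) -> tuple[pd.DataFrame, dict]:
    """Share of multimappers among the reads touching each group.

    A read "maps to" a group when at least one of its mappings overlaps at
    least one copy by >= 1 base.  Groups touched by no read have an undefined
    fraction and are excluded from the threshold-share denominator; the total
    group count is reported separately.
    """
    index = build_copy_index(groups)
    touch = {g.name: {"unimapper": 0, "multimapper": 0} for g in groups}
    for read in reads:
        cls = "multimapper" if read.is_multimapper else "unimapper"
        touched: set[str] = set()
        for m in read.mappings:
            tree = index.get(m.chrom)
            if tree is None:
                continue
            for iv in tree.overlap(m.start, m.end):
                group_name, copy = iv.data
                if overlap_length(m, copy) > 0:
                    touched.add(group_name)
        for name in touched:
            touch[name][cls] += 1

    rows = []
    for g in groups:
        n_uni, n_multi = touch[g.name]["unimapper"], touch[g.name]["multimapper"]
        n = n_uni + n_multi
        rows.append({
            "group": g.name,
            "n_unimappers": n_uni,
            "n_multimappers": n_multi,
            "n_reads": n,
            "multimapper_fraction": (n_multi / n) if n else float("nan"),
        })
    df = pd.DataFrame(rows)
    touched_df = df[df["n_reads"] > 0]
    n_above = int((touched_df["multimapper_fraction"] >= threshold).sum())
    summary = {
        "threshold": threshold,
        "n_groups_total": len(groups),
        "n_groups_touched": len(touched_df),
        "n_groups_at_or_above": n_above,
        "share_at_or_above_among_touched":
            (n_above / len(touched_df)) if len(touched_df) else float("nan"),
    }
    return df, summary


def aggregate_by_clade(
    coverage: pd.DataFrame,
    groups: Sequence[TEGroup],
    clade_ordering: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Sum coverage per clade and read class; groups without a clade are excluded.

    Also reports the number of TE copies and groups per clade.  Rows are
    ordered by ``clade_ordering`` when given (youngest first).
    """
    clade_copies: dict[str, int] = defaultdict(int)
    clade_groups: dict[str, int] = defaultdict(int)
    for g in groups:
        if g.clade is not None:
            clade_copies[g.clade] += g.n_copies
            clade_groups[g.clade] += 1

    df = coverage[coverage["clade"].notna()]
    agg = (df.groupby(["clade", "class"], as_index=False)["coverage"].sum())
    agg["n_te_copies"] = agg["clade"].map(clade_copies)
    agg["n_groups"] = agg["clade"].map(clade_groups)
    if clade_ordering is not None:
        order = {c: i for i, c in enumerate(clade_ordering)}
        agg = agg.sort_values(
            by=["clade", "class"],
            key=lambda col: col.map(order) if col.name == "clade" else col,
        ).reset_index(drop=True)
    return agg
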