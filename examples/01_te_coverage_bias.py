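"""How discarding multimappers erases the signal of young repeat families.

Builds a synthetic genome with a "young" repeat family (20 near-identical
copies, 0.5% divergence) and an "old" one (20 copies, 15% divergence), draws
4000 single-end reads from the copies, aligns them exhaustively, and compares
unique-only coverage with multimapper-aware fractional coverage per family.
"""

import tempfile
from pathlib import Path

from ambiquant.alignment import FilterConfig, load_read_mappings
from ambiquant.annotation import merge_same_name, parse_repeat_annotation
from ambiquant.synthetic import make_fixture
from ambiquant.te_coverage import te_group_coverage

with tempfile.TemporaryDirectory() as tmp:
    bundle = make_fixture("young_vs_old_te", Path(tmp), seed=7)
    reads = list(load_read_mappings(
        bundle.paths["sam"], FilterConfig(keep_reference_pattern=None)))
    groups = merge_same_name(
        parse_repeat_annotation(bundle.paths["repeats_bed"], "bed6"))

n_multi = sum(r.is_multimapper for r in reads)
print(f"{len(reads)} reads aligned; "
      f"{100 * n_multi / len(reads):.1f}% are multimappers")

cov = te_group_coverage(reads, groups)
pivot = cov.pivot(index="group", columns="class", values="coverage")
print("\ncoverage per family (fractional read counts):")
print(f"{'family':<10}{'unique-only':>14}{'multimapper':>14}{'all':>10}"
      f"{'unique share':>14}")
for name, row in pivot.iterrows():
    print(f"{name:<10}{row['unimapper']:>14.1f}{row['multimapper']:>14.1f}"
          f"{row['all']:>10.1f}{row['unimapper'] / row['all']:>14.3f}")

print("\nA unique-only analysis sees almost none of the young family's reads;"
      "\nfractional assignment recovers them without inflating the old family.")
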