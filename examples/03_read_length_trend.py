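"""Shorter reads multimap more: the effect of 3' trimming on ambiguity.

Simulates 2x100 bp paired reads over a genome with an 8-copy repeat family at
4% divergence, trims them to 25/50/75/100 bp from the 3' end, realigns at each
length, and reports the multimapping fragment fraction per length.
"""

import tempfile
from pathlib import Path

from ambiquant.alignment import load_fragment_mappings
from ambiquant.synthetic import TRIM_LENGTHS, make_fixture

with tempfile.TemporaryDirectory() as tmp:
    bundle = make_fixture("trim_series", Path(tmp), seed=7)
    print(f"{'read length':>12}{'fragments':>12}{'multimapper %':>15}")
    for L in TRIM_LENGTHS:
        frags = list(load_fragment_mappings(bundle.paths["sams_by_length"][L]))
        pct = 100 * sum(f.is_multimapper for f in frags) / len(frags)
        print(f"{L:>10}bp{len(frags):>12}{pct:>15.2f}")

print("\nThe same library looks dramatically more ambiguous at 25 bp than at"
      "\n100 bp: read length alone moves reads between the unique and"
      "\nmultimapping classes.")
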