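"""Measure binding-pocket conservation across a receptor family alignment.

Plants an alignment in which two receptors share 73% identity (82%
similarity) over 100 pocket-lining columns, then recovers those numbers and
summarizes per-column conservation as a bits logo matrix.
"""

import math

import ligandpath as lp
from ligandpath import synthetic as syn
from ligandpath.synthetic import ColumnIdentityPlan

positions = list(range(100))
aln = syn.make_alignment(176, 120,
                         ColumnIdentityPlan(positions, 0.73, 0.82), seed=1)

cons = lp.pocket_identity(aln, "seq0001", "seq0002", positions)
print(f"pocket identity   : {cons.identity_pct:.1f}%")
print(f"pocket similarity : {cons.similarity_pct:.1f}% "
      f"(same physicochemical group)")
print(f"columns compared  : {cons.n_compared}")

logo = lp.logo_matrix(aln, positions[:5], units="bits")
print("\ninformation content of the first 5 pocket columns (bits, "
      f"max {math.log2(20):.2f}):")
print((logo.sum(axis=1)).round(2).to_string())
print("High identity over pocket columns across a family marks a conserved "
      "binding site; per-column bits pinpoint which positions are invariant.")
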