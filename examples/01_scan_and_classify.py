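"""Detect conserved segments in a dehydrin and type its architecture.

Builds a synthetic three-F-copy dehydrin (Y2SK2+F3, the architecture of
acidic multi-F dehydrins), scans it for Y/S/K/F segments and prints
the located coordinates and the YSK shorthand the classifier assigns.
"""

from dehydrin.architecture import classify_architecture
from dehydrin.motif_scan import scan_all
from dehydrin.synthetic_data import simulate_dehydrin

sim = simulate_dehydrin(spec="Y2SK2+F3", mutation_rate=0.0, seed=42)
print(f"synthetic protein ({len(sim.record.residues)} aa)")
print()

matches = scan_all(sim.record)
for m in matches:
    print(f"  {m.motif:<10} {m.start:>4}-{m.end:<4} {m.matched}")

call = classify_architecture(matches)
print()
print(f"architecture: {call.shorthand}  (alias {call.f_alias}, type {call.type_label})")
# Each line above is one located segment with its 1-based span; the final
# shorthand counts the copies: 3 expanded F-segments, 2 Y, 1 S-tract, 2 K.
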