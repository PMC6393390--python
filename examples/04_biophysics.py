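"""Charge, hydropathy, pI and mass of the conserved segments.

Compares the expanded F-segment with the K-segment consensus: the F-segment
is more acidic (net charge -3 vs +2) while both are strongly hydrophilic
(negative GRAVY on the Kyte-Doolittle scale).
"""

from dehydrin.biophysics import (
    charged_summary,
    gravy,
    isoelectric_point,
    molecular_weight,
    net_formal_charge,
)
from dehydrin.motif_scan import F_EXPANDED, K_SEGMENT

for name, seq in (("expanded F-segment", F_EXPANDED), ("K-segment", K_SEGMENT)):
    print(f"{name}: {seq}")
    print(f"  charged residues : {charged_summary(seq)}")
    print(f"  net formal charge: {net_formal_charge(seq):+d}")
    print(f"  GRAVY            : {gravy(seq):.3f}")
    print(f"  pI               : {isoelectric_point(seq)}")
    print(f"  MW               : {molecular_weight(seq):.1f} Da")
    print()
# K3E5D2R1 gives the F-segment its net -3; K5E2D1 gives the K-segment +2.
# Both GRAVY values are negative: the segments are hydrophilic, as expected
# for intrinsically disordered stress proteins.
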