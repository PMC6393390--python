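"""Deduce a protein from a cDNA clone by longest-ORF search.

Builds a toy full-length cDNA (5' UTR + coding sequence + 3' UTR) around a
K1-type dehydrin, then recovers the peptide with the forward-3-frame ORF
finder and verifies it by in-silico translation.
"""

from dehydrin.seqio import SequenceRecord, find_longest_orf, translate
from dehydrin.synthetic_data import simulate_dehydrin

protein = simulate_dehydrin("K1", seed=5).record.residues

# back-translate with a fixed codon per residue for a reproducible toy cDNA
codon = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
cds = "ATG" + "".join(codon[aa] for aa in protein) + "TAA"
cdna = SequenceRecord("clone1", "GCAGCA" + cds + "TTTTTT", moltype="nucleotide")

call = find_longest_orf(cdna, min_aa=20)
print(f"ORF: frame {call.frame}, {call.start}-{call.end} "
      f"({len(call.peptide)} aa peptide)")
assert call.peptide == "M" + protein
assert translate(cds[:-3]) == "M" + protein
print("deduced peptide matches the planted protein")
# The longest ATG-to-stop frame recovers exactly the planted coding sequence;
# UTRs are ignored and the stop codon is excluded from the peptide.
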