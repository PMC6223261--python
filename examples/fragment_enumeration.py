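"""Enumerate labeled ring-opening fragments of one cyclic peptide.

Fragmentation of a cyclic peptide starts with a single ring-opening
event; each of the N openings seeds its own b-ion ladder, so ion counts
grow with N^2. Labels follow the Ngoka-Gross convention b_nJZ (ion type,
residue count, the residue J that became the N-terminus, and the residue
Z preceding it), extended with sequence positions when an adjacency
repeats in the cycle.
"""

from plpmine import enumerate_fragments, annotate_precursor_ions

seq = "GYVFPD"
ions = enumerate_fragments(seq, losses=False, immonium=True)

print(f"{len(ions)} theoretical ions for cyclo-{seq}:")
print(f"{'label':10} {'type':9} {'window':8} {'m/z':>10}")
for f in ions:
    print(f"{f.label:10} {f.ion_type:9} {f.window:8} {f.mz:>10.4f}")
for f in annotate_precursor_ions(seq):
    print(f"{f.label:10} {f.ion_type:9} {f.window:8} {f.mz:>10.4f}")

print(
    "\nb2PF (m/z 213.087) is the Pro-Asp dipeptide acylium from the ring\n"
    "opening N-terminal to Pro — the first member of the diagnostic\n"
    "b2PF-b5PF series of this peptide's published spectrum."
)
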