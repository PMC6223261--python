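# plpmine

Discovery and tandem-MS confirmation of **PawL-derived peptides
(PLPs)** — small head-to-tail cyclic plant peptides (orbitides) whose
sequences are buried inside *PawL1* seed storage albumin precursors and
excised by asparaginyl endopeptidase (AEP). The package is for
researchers who have assembled seed transcriptomes and centroided
LC-MS/MS peak lists and want to go from transcripts to confirmed cyclic
peptide sequences, plus the catalog-level statistics that describe the
family.

## What it computes

**Masses.** A head-to-tail macrocycle's monoisotopic mass is the sum of
its residue masses (cyclization consumes the terminal water):
M(cyclo-s) = Σᵢ m(sᵢ), and the singly protonated precursor is
[M+H]⁺ = M + 1.007276.

**Fragments.** Cyclic-peptide CID begins with a single ring-opening
event; each of the N openings seeds a b-ion ladder (bₙ = window sum +
proton; aₙ = bₙ − CO), so ion counts grow as N². Ions carry
Ngoka–Gross labels `b_nJZ` — n residues, J the residue that became the
N-terminus at the opening, Z the residue before it — extended with
sequence positions (`b3I3I2`) when the (Z, J) adjacency repeats.

**Confirmation.** Matched b-ion series are rendered as sequence
constraints (`b2PF–b5PF` + [M+H]⁺ on cyclo-GYVFPD gives
`[P,D]-G-Y-V-F`: an unordered leading pair, then an ordered walk that
the precursor closes). A candidate is confirmed when its constraints
single it out — against the transcript-derived candidate set, or
against every distinct cyclic arrangement of its residue multiset
(exhaustive mode, with the matched-ion count as primary score and
series structure breaking the exact tie that the reversed cycle always
produces). Ile/Leu, indistinguishable by mass, are resolved from the
transcript.

**Mining.** A rule-based scanner finds PawL1-like precursors in
six-frame translations: hydrophobic ER signal, the conserved Asn, a
5–12 residue span ending at the last Asp followed by a GLDN-type tail
(P1′ small, P2′ Leu, P3′ Asp/Asn), and a Cys-rich albumin region.

**Statistics.** Length histograms, per-position frequency matrices
built per exact length with no alignment, information content
R = log₂20 − (H + e_n) with e_n = 19/(2·n·ln 2), residue composition,
and flanking-site (P1, P1′–P4′) conservation. A transcription of the
published 46-peptide catalog ships with the package.

A seeded synthetic-data generator produces precursor-bearing
transcripts and realistic spectra (ring-opening propensities biased
toward Pro and Ile/Leu–Asp openings, m/z jitter, dropout, noise) for
end-to-end validation; see `docs/methods.md`.

## Worked example

```python
>>> from plpmine import CyclicPeptide, cyclic_monoisotopic_mass, match_spectrum
>>> from plpmine.synthetic_data import series_spectrum
>>> cyclic_monoisotopic_mass("GYVFPD")
678.3013269517799
>>> sp = series_spectrum("GYVFPD", (5, 4, 1))   # series from openings at P, F, G
>>> rep = match_spectrum(sp, CyclicPeptide(encoded_seq="GYVFPD"), tol=0.01)
>>> for s, c in zip(rep.series, rep.constraints()):
...     print(s.label_range(), "->", c)
b2GD-b5GD -> [G,Y]-V-F-P-D
b2FV-b5FV -> [F,P]-D-G-Y-V
b2PF-b5PF -> [P,D]-G-Y-V-F
```

The mass, 678.301 Da, reproduces the catalog value for this peptide.
Each line reads one ring opening's b-ion series: `b2PF-b5PF` says that
after opening N-terminal to Pro the first two residues are P and D in
unknown order, then G, Y, V follow in order, and the matched [M+H]⁺
closes the ring with F — jointly these pin down cyclo-GYVFPD.

The same flow scales up: `examples/` contains one short script per
capability (mass prediction, fragment enumeration, sequence
confirmation, mining a synthetic transcriptome end-to-end, catalog
conservation), and a thin CLI mirrors the stages:

```sh
plpmine simulate --seed 1 --n-plps 6 --out demo/
plpmine run-all --fasta demo/transcripts.fasta --mgf demo/spectra.mgf --out demo/out
plpmine stats
plpmine fragment --seq GYVFPD --immonium
```

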