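# Methods

`plpmine` implements transcriptome-guided discovery and tandem-MS
confirmation of PawL-derived peptides (PLPs): small head-to-tail cyclic
peptides (orbitides) buried inside *PawL1* seed storage albumin
precursors in the Asteroideae. This note records the models, parameter
choices and numerical conventions behind each stage, and what the
synthetic-data results do and do not establish.

## The biological model

A PawL1 preproalbumin has the architecture

    ER signal — spacer — Asn | PLP … Asp | P1′ P2′ P3′ P4′ — albumin (Cys-rich)

Asparaginyl endopeptidase (AEP) cleaves after the absolutely conserved
Asn preceding the peptide and after the peptide's proto-C-terminal Asp,
closing the macrocycle by transpeptidation. The trailing residues are a
GLDN-type tail: a small P1′ residue (Gly/Ser/Ala, sometimes Arg), a
strongly conserved P2′ Leu required for macrocyclization, and a P3′
Asp/Asn that is itself an AEP maturation point preceding the albumin
small subunit. Mature PLPs are 5–12 residues, hydrophobic, Cys-free,
and invariably end in Asp.

## Mass model (`peptide_core`)

Cyclic monoisotopic mass = Σ residue masses; the head-to-tail amide bond
consumes the terminal water, so the linear mass is the cyclic mass +
18.010565 Da. Residue masses and the proton/water/ammonia/CO constants
are taken from pyteomics' monoisotopic tables (≥ 6 decimals), not typed
by hand; the packaged 46-peptide catalog is the en-bloc validation —
every printed mass must be reproduced to ±0.001 Da or loading fails.
Reported masses are rounded half-up to 3 decimals (the catalog's
precision); internal arithmetic keeps full precision. Nonstandard or
modified residues are rejected outright, never skipped.

Macrocycle identity: two encoded sequences denote the same cycle iff
their lexicographically smallest rotations agree. Reversal is *not*
identified — a retro cycle is a different molecule (see "retro
ambiguity" below for why this matters analytically).

## Fragment enumeration (`fragmentation`)

Collision-induced dissociation of a cyclic peptide begins with a single
ring-opening event; each of the N openings linearizes the ring into an
acylium from which b ions (window sum + proton), a ions (b − CO),
water/ammonia losses (applied at most once per ion) and immonium ions
(residue − CO + proton) derive. Plain b ions are generated for
n = 1..N−1 per opening — N(N−1) ions, the quadratic growth that makes
cyclic peptides hard to sequence. The full-ring acylium b_N is the same
species for every opening (it equals the cyclic [M+H]⁺) and is emitted
once, labeled `bN`.

Labels follow the Ngoka–Gross convention `x_nJZ` (ion type, residue
count, J = new N-terminal residue at the ring opening, Z = the residue
preceding it). When the ordered adjacency (Z, J) occurs more than once
around the cycle the bare label is ambiguous, and J and Z carry their
1-based positions in the encoded sequence (`b3I3I2`). The same rule is
applied to a ions for uniformity. y ions are not generated: b-type
chemistry dominates cyclic fragmentation and annotated spectra in this
family use a/b/immonium only.

## Matching and confirmation (`matching`)

Fragment tolerances are absolute m/z windows, ±0.02 Da for Q-TOF data
and ±0.01 Da for Orbitrap — absolute, not ppm, following the practice
of the source study. Peak assignment is one-to-one: each observed peak
may annotate at most one theoretical ion, nearest error wins, ties go
to the higher-intensity peak. This stops a single noise peak from
inflating coverage. Increasing the tolerance can therefore only add
matches (monotonicity, property-tested).

From the matched plain-b ions, maximal contiguous series per ring
opening are extracted and rendered as sequence constraints: the first
matched b_n contributes an unordered bracket of its n residues, each
consecutive b-step one ordered residue, and a matched [M+H]⁺ closes the
ring (`[P,D]-G-Y-V-F`). Adjacency coverage counts a backbone bond as
evidenced when two consecutive matched ions of one opening (treating
[M+H]⁺ as b_N) differ by exactly that residue.

Confirmation has three modes:

* **constraint** (pipeline default): every series constraint must be
  satisfiable on the candidate cycle and on no other candidate in the
  transcript-derived set. This formalizes the study's actual decision —
  agreement between spectrum-derived constraints and the transcript
  prediction.
* **exhaustive** (N ≤ 9): every distinct cyclic arrangement of the
  candidate's residue multiset is scored against the spectrum. The
  primary score is the matched-ion count (vectorized window sums);
  count ties are broken by series structure — longest contiguous
  matched b-run, then ring-opening propensity plausibility. Confirmed
  means strictly top; the reported margin is the count margin (0 when
  series structure decided).
* **sampled**: as exhaustive over k seeded random arrangements
  (default 50,000) for rings too large to enumerate. The N ≤ 9 bound
  keeps the enumeration desk-scale (≤ 8!/symmetry cycles).

Two physical identifiability limits shape this design:

* **Ile/Leu are isobaric.** No fragment mass distinguishes them, so the
  arrangement space is built over the I/L-collapsed multiset and the
  final I/L assignment comes from the transcript (`resolve_isobaric`),
  exactly as in the study.
* **The retro ambiguity.** Every contiguous window of a reversed cycle
  is a reversed window of the original with the same mass, so a cycle
  and its retro cycle have *identical* b-ion m/z multisets. No score
  that depends only on which m/z values are present can separate them.
  Series *structure* can: on realistic spectra (ladders from a few
  favored openings) the retro candidate explains the same peaks only as
  scattered short runs at unfavored openings. For small rings with no
  favored opening (e.g. a Pro-free 5-mer) even that fails, and the
  retro cycle is genuinely indistinguishable by this evidence; the
  catalog-wide test documents this single exception rather than hiding
  it.

Candidate ranking sorts by matched b-ion count, summed matched relative
intensity (relative to the spectrum base peak, rounded to 6 decimals so
isospectral candidates tie exactly rather than by float summation
order), longest contiguous series, ring-opening propensity plausibility
(Pro ×5, Ile/Leu–Asp ×3 — the literature priors for favored ring
cleavages), and finally canonical-rotation lexicographic order for
determinism.

## Precursor mining (`precursor_mining`)

The scanner is a rule-based reconstruction of a homology-guided search
whose details are not among this package's inputs; every threshold is a
configurable `MiningParams` field. Six-frame translations are segmented
at stops; segments ≥ 40 aa are scanned for:

1. an ER signal: maximum mean Kyte–Doolittle hydropathy over any
   8-residue window in the first 30 residues ≥ 2.5 (planted and real
   signal h-regions score well above 3; random translations rarely do);
2. an Asn at 0-based position 15–60;
3. a 5–12 residue span after the Asn ending at the **last** Asp whose
   trailing residues match P1′ ∈ [GSAR], P2′ = L, P3′ ∈ [DN] (the
   GLDN-type tail). The last Asp, not the first: observed PLPs contain
   internal Asp and a first-Asp rule would truncate them. If no Asp
   qualifies, the span is delimited by the first downstream tail match
   and the candidate is classed `asp_lacking` — the degenerate
   architecture of precursors that lost their peptide;
4. albumin evidence: ≥ 6 Cys in the 120 residues after the tail.

With these defaults the scanner recovers 100% of planted precursors
with exact span boundaries and produced 0 false candidates in 30,000
random 600-nt transcripts (rate < 10⁻⁴). Coordinates are 0-based
half-open; minus-strand features are reported in plus-strand
coordinates. No start codon is required (partial transcripts are
common). PawS1-type Cys-containing buried peptides are out of scope.

## Catalog statistics (`catalog_stats`)

Statistics are computed over unique peptides (exact encoded sequence):
the same peptide can occur in several taxa, and the published per-length
counts (11 seven-mers, 25 eight-mers of 46 unique) hold only under
uniqueness. Species counting collapses infraspecific taxa (var./ssp.)
onto the binomial, giving the published 17. Conservation displays are
built per exact length with no alignment and no gaps — aligning 5–12-mer
peptides inserts more gap than signal. Position information content is
R_i = log₂20 − (H_i + e_n) bits with the small-sample correction
e_n = 19/(2·n·ln 2), clipped at 0; the numeric matrices are the tested
artifact and the matplotlib logo rendering is a convenience.

## Synthetic data (`synthetic_data`)

The generator emulates the statistical structure the analysis assumes,
as pure functions of (params, seed):

* **Peptides**: length drawn from the catalog's empirical distribution
  (counts 5:1, 6:3, 7:11, 8:25, 9:3, 10:2, 12:1), interior residues
  from a hydrophobic-weighted distribution (I/L/V/P/F dominant, no
  Cys), Gly forced at position 1 with probability 0.6, Asp forced last.
* **Precursors**: Met + 19 hydrophobic residues (signal stub), a polar
  Asn-free spacer of 15–30 residues (keeping the conserved Asn unique
  and inside the scanner's position window), Asn + PLP + GLDN + a
  130-residue albumin-like region with 8 forced Cys. The albumin
  alphabet excludes Leu and Asn so the planted AEP site is the only
  architectural match on the transcript — a deliberate simplification
  relative to real albumins. Reverse translation uses uniform synonymous
  codons (no codon-usage table; mining operates on translations). The 5′
  UTR ends in an in-frame stop so the translated segment starts at the
  Met.
* **Spectra**: each ring opening contributes its b-ladder independently
  with probability min(1, 0.6 × propensity), where openings N-terminal
  to Pro carry weight 5 and Ile/Leu–Asp openings weight 3 (the
  qualitative literature preferences, given invented magnitudes); real
  spectra show ion counts growing ~N² with favored openings dominant.
  Ions start at b2 (b1 acylium ions are rarely observed under CID).
  Per-ion detection probability 0.8 by default, Gaussian m/z jitter
  (sd 0.005 Da), log-normal intensities (μ=0, σ=1), the jittered
  precursor, and 30 uniform noise peaks over [100, precursor m/z]
  scaled below the true-ion median. A fixed-size opening subset mode
  exists for experiments.

What the generator does **not** emulate: isotope envelopes, charge
states above 2, chromatography and retention, real codon usage, real
albumin sequence composition, collision-energy dependence (the opening
propensities are a static stand-in), and homology between related
genes. Passing end-to-end tests therefore demonstrates the pipeline's
logic — recovery, ranking, confirmation under jitter/dropout/noise —
not performance on real seed extracts.

## Problem sizes and runtimes

The test suite validates the fragmentation enumerator against a
brute-force cyclic-window oracle over all ~87,000 sequences of length
3–8 on a 4-letter alphabet; end-to-end recovery uses 20 planted
precursors, 20 decoy transcripts and 120 simulated spectra, each ranked
against 10 mass-matched decoy arrangements (measured rank-first rate
~97% across five independent 200-spectrum replicates; the required
bound is 95%). Exhaustive uniqueness enumerates all 120 arrangements of
the 6-residue worked example and up to ~5,000 for 8-mers. The full
suite runs in under a minute on one CPU.

## Known limitations

* The precursor scanner is a motif reconstruction, not the original
  homology search; agreement with the original tool on real
  transcriptomes is unverified.
* Confirmation certainty is bounded by the retro and I/L ambiguities
  described above; both are properties of the physics, not the code.
* Intensity information is used only as a ranking tie-break; no
  intensity prediction is attempted.
* FDR estimation at scale (target-decoy) and spectral-library scoring
  are out of scope.
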