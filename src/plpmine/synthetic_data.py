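"""Seeded generators for precursor transcripts and cyclic-peptide spectra.

The generator emulates the statistical structure the analysis assumes:

* PLP sequences with the catalog's length distribution (7- and 8-mers
  dominant), a hydrophobic residue bias, frequent Gly at position 1 and
  the invariant proto-C-terminal Asp;
* preproalbumin-like precursor proteins (hydrophobic ER-signal stub,
  polar spacer, conserved Asn, the PLP, a GLDN-type tail and a Cys-rich
  albumin-like region) reverse-translated with uniform synonymous codons;
* MS/MS spectra whose ring-opening propensity is biased toward openings
  N-terminal to Pro and at Ile/Leu-Asp bonds, with m/z jitter, ion
  dropout, log-normal intensities and uniform noise peaks.

All outputs are pure functions of (params, seed): the same seed gives
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .peptide_core import (
    RESIDUE_MASSES,
    CyclicPeptide,
    canonical_rotation,
    cyclic_monoisotopic_mass,
    mz_from_mass,
)
from .fragmentation import RingOpening, enumerate_fragments
from .matching import Spectrum

# Length distribution of the known catalog (counts over 46 unique PLPs).
DEFAULT_LENGTH_WEIGHTS: dict[int, float] = {5: 1, 6: 3, 7: 11, 8: 25, 9: 3, 10: 2, 12: 1}

# Interior residue propensities: hydrophobic-dominated, Cys-free.
DEFAULT_RESIDUE_WEIGHTS: dict[str, float] = {
    "I": 10, "L": 10, "V": 8, "P": 8, "F": 8, "G": 6, "A": 4, "T": 3,
    "Y": 3, "S": 2, "D": 2, "E": 1, "Q": 1, "H": 1, "K": 1, "R": 1,
    "W": 0.5, "M": 0.5, "N": 0.3,
}

_SIGNAL_ALPHABET = "LIVFA"
_SPACER_ALPHABET = "STEQAGPKRDH"  # polar, Asn-free so the conserved Asn is unique
# Albumin-like region: Leu- and Asn-free so the planted AEP site is the only
# architectural match on the transcript; Cys content is forced separately.
_ALBUMIN_ALPHABET = "ACDEFGHIKMPQRSTVWY"

_CODONS: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    if not _CODONS:
        from Bio.Data.CodonTable import standard_dna_table

        for codon, aa in sorted(standard_dna_table.forward_table.items()):
            _CODONS.setdefault(aa, []).append(codon)
    return _CODONS


@dataclass
class SimulationParams:
    """Study conditions for the synthetic datasets."""

    seed: int = 0
    n_plps: int = 20
    n_decoy_transcripts: int = 20
    spectra_per_plp: int = 1
    length_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS)
    )
    residue_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUE_WEIGHTS)
    )
    gly1_prob: float = 0.6
    # ring-opening propensities
    pro_multiplier: float = 5.0  # opening N-terminal to Pro
    ild_multiplier: float = 3.0  # opening at an Ile/Leu-Asp bond
    # Each opening contributes its series independently with probability
    # min(1, opening_rate * weight): favored openings (Pro, Ile/Leu-Asp)
    # are essentially always represented, baseline ones stochastically —
    # fragmentation can initiate at any ring bond, so observed ion counts
    # grow roughly with the square of the residue count. Setting
    # ``n_openings`` instead samples a fixed-size subset of openings.
    opening_rate: float = 0.6
    n_openings: int | None = None
    min_b: int = 2  # b1 acylium ions are rarely observed under CID
    detection_prob: float = 0.8  # per-ion detection (1 - dropout)
    mz_jitter_sd: float = 0.005  # Da
    n_noise_peaks: int = 30
    noise_mz_min: float = 100.0
    intensity_mu: float = 0.0  # log-normal intensity model
    intensity_sigma: float = 1.0
    noise_scale: float = 0.3  # noise intensity scale vs true-ion median
    decoys_per_spectrum: int = 10
    spacer_min: int = 15
    spacer_max: int = 30
    albumin_len: int = 130
    albumin_n_cys: int = 8

    def validate(self) -> None:
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError("detection_prob must be in [0, 1]")
        if not 0.0 <= self.gly1_prob <= 1.0:
            raise ValueError("gly1_prob must be in [0, 1]")
        for name in ("pro_multiplier", "ild_multiplier"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TruthRecord:
    transcript_id: str
    plp_seq: str
    protein: str
    asn_position: int  # 0-based in the protein
    plp_span: tuple[int, int]  # half-open, protein coordinates
    spectrum_ids: list[str] = field(default_factory=list)


def _weighted_choice(rng: np.random.Generator, items: list, weights: list[float], size=None):
    p = np.asarray(weights, dtype=float)
    p = p / p.sum()
    return rng.choice(items, size=size, p=p)


def random_plp(rng: np.random.Generator, params: SimulationParams | None = None) -> str:
    """Draw one PLP-like sequence: biased length/composition, terminal Asp."""
    if params is None:
        params = SimulationParams()
    lengths = sorted(params.length_weights)
    L = int(_weighted_choice(rng, lengths, [params.length_weights[x] for x in lengths]))
    residues = sorted(params.residue_weights)
    weights = [params.residue_weights[r] for r in residues]
    interior = list(_weighted_choice(rng, residues, weights, size=L - 1))
    if rng.random() < params.gly1_prob:
        interior[0] = "G"
    return "".join(interior) + "D"


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    table = _codon_table()
    return "".join(str(rng.choice(table[aa])) for aa in protein)


def build_precursor(
    plp: str, rng: np.random.Generator, params: SimulationParams | None = None,
    transcript_id: str = "tx",
) -> tuple[str, str, TruthRecord]:
    """Embed one PLP in a preproalbumin-like protein and its transcript.

    Protein layout: Met + 19 hydrophobic residues (ER-signal stub), a
    polar spacer, the conserved Asn, the PLP, the GLDN tail, then an
    albumin-like region with forced Cys content. The transcript is the
    uniform-synonymous-codon reverse translation framed by a 5' UTR ending
    in an in-frame stop (so the translated segment starts at the Met) and
    a 3' UTR after the stop codon.
    """
    if params is None:
        params = SimulationParams()
    signal = "M" + "".join(_weighted_choice(rng, list(_SIGNAL_ALPHABET), [4, 4, 3, 2, 2], size=19))
    spacer_len = int(rng.integers(params.spacer_min, params.spacer_max + 1))
    spacer = "".join(rng.choice(list(_SPACER_ALPHABET), size=spacer_len))
    albumin = list(rng.choice(list(_ALBUMIN_ALPHABET), size=params.albumin_len))
    cys_pos = rng.choice(params.albumin_len, size=params.albumin_n_cys, replace=False)
    for p in cys_pos:
        albumin[p] = "C"
    protein = signal + spacer + "N" + plp + "GLDN" + "".join(albumin)
    asn_pos = len(signal) + spacer_len
    span = (asn_pos + 1, asn_pos + 1 + len(plp))
    cds = _reverse_translate(protein, rng)
    utr5 = "".join(rng.choice(list("ACGT"), size=27)) + "TAA"
    utr3 = "".join(rng.choice(list("ACGT"), size=30))
    transcript = utr5 + cds + "TAA" + utr3
    truth = TruthRecord(
        transcript_id=transcript_id,
        plp_seq=plp,
        protein=protein,
        asn_position=asn_pos,
        plp_span=span,
    )
    return protein, transcript, truth


def opening_weights(seq: str, params: SimulationParams) -> np.ndarray:
    """Ring-opening propensity per 1-based opening index.

    Baseline 1.0, multiplied up when the new N-terminus is Pro (cleavage
    N-terminal to Pro) or when the broken bond is Ile/Leu-Asp.
    """
    w = np.ones(len(seq))
    for j in range(1, len(seq) + 1):
        op = RingOpening(seq, j)
        if op.j_residue == "P":
            w[j - 1] *= params.pro_multiplier
        if op.z_residue in "IL" and op.j_residue == "D":
            w[j - 1] *= params.ild_multiplier
    return w


def simulate_spectrum(
    seq: str,
    params: SimulationParams | None = None,
    rng: np.random.Generator | None = None,
    spectrum_id: str = "sim",
) -> Spectrum:
    """One simulated MS/MS spectrum of the cyclic peptide ``seq``."""
    if params is None:
        params = SimulationParams()
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = len(seq)
    w = opening_weights(seq, params)
    if params.n_openings is not None:
        k = min(params.n_openings, n)
        chosen = set(
            int(c) for c in rng.choice(np.arange(1, n + 1), size=k, replace=False, p=w / w.sum())
        )
    else:
        p_open = np.minimum(1.0, params.opening_rate * w)
        chosen = {j + 1 for j in range(n) if rng.random() < p_open[j]}
        if not chosen:
            chosen = {int(rng.choice(np.arange(1, n + 1), p=w / w.sum()))}
    ions = [
        f
        for f in enumerate_fragments(seq, ion_types=("b",), min_n=params.min_b)
        if f.opening is not None and f.opening.opening_index in chosen
    ]
    keep = rng.random(len(ions)) < params.detection_prob
    if len(ions) and not keep.any():
        keep[rng.integers(len(ions))] = True  # a planted spectrum keeps >= 1 true ion
    kept = [ion for ion, k_ in zip(ions, keep) if k_]

    mh = mz_from_mass(cyclic_monoisotopic_mass(seq), 1)
    mz = [ion.mz + rng.normal(0.0, params.mz_jitter_sd) for ion in kept]
    inten = list(rng.lognormal(params.intensity_mu, params.intensity_sigma, size=len(kept)))
    # precursor surviving into the MS/MS scan
    mz.append(mh + rng.normal(0.0, params.mz_jitter_sd))
    inten.append(float(rng.lognormal(params.intensity_mu + 1.0, params.intensity_sigma)))

    if params.n_noise_peaks and len(inten):
        med = float(np.median(inten))
        noise_mz = rng.uniform(params.noise_mz_min, max(mh, params.noise_mz_min + 1), size=params.n_noise_peaks)
        noise_int = rng.lognormal(params.intensity_mu, params.intensity_sigma, size=params.n_noise_peaks)
        noise_int = noise_int * params.noise_scale * med / max(np.median(noise_int), 1e-12)
        mz.extend(noise_mz.tolist())
        inten.extend(noise_int.tolist())

    return Spectrum(
        id=spectrum_id,
        precursor_mz=mh + rng.normal(0.0, params.mz_jitter_sd),
        precursor_charge=1,
        peaks_mz=np.array(mz),
        peaks_intensity=np.array(inten),
    )


def noiseless_spectrum(seq: str, *, min_b: int = 2, spectrum_id: str = "ideal") -> Spectrum:
    """Degenerate simulation: every b-ion of every opening plus [M+H]+, no noise.

    With ``min_b=1`` the peak set is the complete theoretical fragment set.
    """
    ions = enumerate_fragments(seq, ion_types=("b",), min_n=min_b)
    mh = mz_from_mass(cyclic_monoisotopic_mass(seq), 1)
    mz = sorted({round(f.mz, 6) for f in ions if f.n < len(seq)} | {round(mh, 6)})
    return Spectrum(
        id=spectrum_id,
        precursor_mz=mh,
        precursor_charge=1,
        peaks_mz=np.array(mz),
        peaks_intensity=np.ones(len(mz)),
    )


def series_spectrum(
    seq: str,
    openings: tuple[int, ...],
    *,
    min_b: int = 2,
    spectrum_id: str = "series",
) -> Spectrum:
    """Noiseless spectrum carrying complete b-ladders for chosen openings.

    This is the shape of a real annotated spectrum: a handful of favored
    ring openings each contribute a contiguous b2..b(N-1) series, plus the
    protonated molecule. ``openings`` are 1-based positions of the residues
    that become the N-terminus.
    """
    ions = [
        f
        for f in enumerate_fragments(seq, ion_types=("b",), min_n=min_b)
        if f.opening is not None and f.opening.opening_index in set(openings)
    ]
    mh = mz_from_mass(cyclic_monoisotopic_mass(seq), 1)
    mz = sorted({round(f.mz, 6) for f in ions} | {round(mh, 6)})
    return Spectrum(
        id=spectrum_id,
        precursor_mz=mh,
        precursor_charge=1,
        peaks_mz=np.array(mz),
        peaks_intensity=np.ones(len(mz)),
    )


def favored_openings(seq: str, k: int = 3, params: SimulationParams | None = None) -> tuple[int, ...]:
    """The ``k`` highest-propensity ring openings (deterministic order)."""
    w = opening_weights(seq, params or SimulationParams())
    order = sorted(range(1, len(seq) + 1), key=lambda j: (-w[j - 1], j))
    return tuple(order[: min(k, len(seq))])


def mass_matched_decoys(seq: str, k: int, rng: np.random.Generator) -> list[CyclicPeptide]:
    """``k`` distinct cyclic arrangements of the residue multiset of ``seq``.

    Decoys share the exact precursor mass, so they are only separable by
    fragment evidence.
    """
    own = canonical_rotation(seq)
    decoys: dict[str, CyclicPeptide] = {}
    residues = list(seq)
    attempts = 0
    while len(decoys) < k and attempts < 200 * (k + 1):
        attempts += 1
        rng.shuffle(residues)
        s = "".join(residues)
        canon = canonical_rotation(s)
        if canon != own and canon not in decoys:
            decoys[canon] = CyclicPeptide(encoded_seq=s, name=f"decoy_{len(decoys)}")
    return list(decoys.values())


def _write_fasta(records: list[tuple[str, str]], path: Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_mgf(spectra: list[Spectrum], path: Path) -> None:
    """Deterministically formatted MGF writer."""
    with open(path, "w") as fh:
        for sp in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={sp.id}\n")
            fh.write(f"PEPMASS={sp.precursor_mz:.5f}\n")
            fh.write(f"CHARGE={sp.precursor_charge}+\n")
            for m, i in zip(sp.peaks_mz, sp.peaks_intensity):
                fh.write(f"{m:.5f} {i:.4f}\n")
            fh.write("END IONS\n")


def make_dataset(
    params: SimulationParams, out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Write transcripts.fasta, spectra.mgf and truth.tsv for one seed.

    Transcripts mix planted precursors with random decoy transcripts; each
    planted PLP gets one or more spectra. Returns the three paths.
    """
    params.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)

    plps: list[str] = []
    seen = set()
    while len(plps) < params.n_plps:
        p = random_plp(rng, params)
        canon = canonical_rotation(p)
        if canon not in seen:
            seen.add(canon)
            plps.append(p)

    records: list[tuple[str, str]] = []
    truths: list[TruthRecord] = []
    for i, plp in enumerate(plps):
        tid = f"planted_{i:03d}"
        _, transcript, truth = build_precursor(plp, rng, params, transcript_id=tid)
        records.append((tid, transcript))
        truths.append(truth)
    for i in range(params.n_decoy_transcripts):
        length = int(rng.integers(400, 900))
        records.append(
            (f"decoy_{i:03d}", "".join(rng.choice(list("ACGT"), size=length)))
        )

    spectra: list[Spectrum] = []
    for truth in truths:
        for r in range(params.spectra_per_plp):
            sid = f"{truth.transcript_id}_ms2_{r}"
            spectra.append(simulate_spectrum(truth.plp_seq, params, rng, spectrum_id=sid))
            truth.spectrum_ids.append(sid)

    fasta = out / "transcripts.fasta"
    mgf = out / "spectra.mgf"
    truth_tsv = out / "truth.tsv"
    _write_fasta(records, fasta)
    write_mgf(spectra, mgf)
    with open(truth_tsv, "w") as fh:
        fh.write("transcript_id\tplp_seq\tasn_position\tspan_start\tspan_end\tspectrum_ids\n")
        for t in truths:
            fh.write(
                f"{t.transcript_id}\t{t.plp_seq}\t{t.asn_position}\t"
                f"{t.plp_span[0]}\t{t.plp_span[1]}\t{','.join(t.spectrum_ids)}\n"
            )
    return fasta, mgf, truth_tsv
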