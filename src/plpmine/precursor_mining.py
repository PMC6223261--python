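"""Mining assembled transcripts for PawL1-like preproalbumin precursors.

A PawL1 precursor is a seed storage albumin preproprotein with a small
cyclic peptide (PLP) buried between the ER signal and the albumin domain:

    ER signal -- spacer -- Asn | PLP ... Asp | P1'-P2'(Leu)-P3'-P4' -- albumin (Cys-rich)

Asparaginyl endopeptidase (AEP) cleaves after the absolutely conserved
Asn and after the PLP's proto-C-terminal Asp, closing the macrocycle by
transpeptidation; the P1' residue is small (Gly/Ser/Ala) or Arg and the
P2' Leu is strongly conserved. The scanner below encodes exactly those
architectural constraints as a rule-based search over six-frame
translations. It is a reconstruction of a homology-guided search whose
details are not part of this package's inputs; all thresholds are
configurable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .peptide_core import (
    CyclicPeptide,
    canonical_rotation,
    cyclic_monoisotopic_mass,
    mz_from_mass,
    round_mass,
)

_NT_RE = re.compile(r"^[ACGTN]+$")


@dataclass(frozen=True)
class TranscriptRecord:
    """An assembled transcript nucleotide sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if not _NT_RE.match(self.seq):
            bad = sorted(set(self.seq) - set("ACGTN"))
            raise ValueError(f"{self.id}: non-nucleotide characters {bad}")


@dataclass(frozen=True)
class OrfTranslation:
    """An open reading segment from one frame/strand of a transcript.

    Coordinates are 0-based half-open nucleotide positions on the + strand
    of the source transcript, regardless of the segment's own strand.
    """

    transcript_id: str
    frame: int  # 1-3
    strand: str  # '+' or '-'
    aa_seq: str
    nt_start: int
    nt_end: int


@dataclass
class MiningParams:
    """Tunable thresholds of the precursor scanner."""

    er_hydropathy_threshold: float = 2.5  # Kyte-Doolittle window mean
    er_window: int = 8
    er_region: int = 30  # search window for the signal, from segment start
    asn_min: int = 15  # allowed 0-based positions of the conserved Asn
    asn_max: int = 60
    span_min: int = 5  # PLP length bounds
    span_max: int = 12
    p1_prime: str = "GSAR"  # allowed P1' residues; P2' is always Leu
    p3_prime: str = "DN"  # P3' precedes the albumin small subunit (GLDN tail)
    min_cys: int = 6  # albumin evidence: Cys count downstream of the tail
    cys_window: int = 120
    min_segment: int = 40  # discard open reading segments shorter than this


@dataclass(frozen=True)
class PrecursorCandidate:
    source: OrfTranslation
    er_signal_score: float
    asn_position: int  # 0-based index of the conserved Asn in aa_seq
    plp_span: tuple[int, int]  # half-open aa indices
    tail: str  # P1'-P4'
    albumin_score: float
    candidate_class: str  # 'plp_with_asp' | 'asp_lacking'

    @property
    def plp_seq(self) -> str:
        return self.source.aa_seq[self.plp_span[0] : self.plp_span[1]]

    @property
    def combined_score(self) -> float:
        return self.er_signal_score + self.albumin_score


def read_fasta(path: str | Path) -> list[TranscriptRecord]:
    return [
        TranscriptRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def six_frame_translate(
    transcript: TranscriptRecord, min_segment: int = 40
) -> list[OrfTranslation]:
    """Translate all six frames and segment at stop codons.

    Segments shorter than ``min_segment`` residues are dropped; codons
    containing N translate to 'X'.
    """
    out: list[OrfTranslation] = []
    L = len(transcript.seq)
    for strand, nt in (("+", transcript.seq), ("-", str(Seq(transcript.seq).reverse_complement()))):
        for frame in (0, 1, 2):
            usable = (len(nt) - frame) // 3
            if usable <= 0:
                continue
            aa = str(Seq(nt[frame : frame + 3 * usable]).translate())
            pos = 0
            for segment in aa.split("*"):
                if len(segment) >= min_segment:
                    # segment spans aa indices [pos, pos+len) of this frame
                    s_nt = frame + 3 * pos
                    e_nt = frame + 3 * (pos + len(segment))
                    if strand == "+":
                        nt_start, nt_end = s_nt, e_nt
                    else:
                        nt_start, nt_end = L - e_nt, L - s_nt
                    out.append(
                        OrfTranslation(
                            transcript.id, frame + 1, strand, segment, nt_start, nt_end
                        )
                    )
                pos += len(segment) + 1  # account for the '*'
    return out


def er_signal_score(aa_seq: str, params: MiningParams) -> float:
    """Max mean Kyte-Doolittle hydropathy over any window in the N-terminal region."""
    region = aa_seq[: params.er_region]
    w = params.er_window
    if len(region) < w:
        return float("-inf")
    best = float("-inf")
    for i in range(len(region) - w + 1):
        window = region[i : i + w]
        if any(c not in KYTE_DOOLITTLE for c in window):
            continue
        best = max(best, sum(KYTE_DOOLITTLE[c] for c in window) / w)
    return best


def _find_span(aa: str, asn: int, params: MiningParams) -> tuple[int, int, str] | None:
    """Locate the PLP span after the Asn at index ``asn``.

    Preferred rule: the span runs from asn+1 to the LAST Asp (inclusive)
    within length bounds whose following residues match the tail pattern:
    P1' in [GSAR], P2' Leu, P3' in [DN] (the GLDN-type tail preceding the
    albumin small subunit). Observed PLPs contain internal Asp, so the
    last qualifying Asp, not the first, delimits the peptide. Fallback:
    with no such Asp, the span is delimited by the first downstream match
    of the tail pattern and the candidate is classed 'asp_lacking'.
    """

    def tail_matches(pos: int) -> bool:
        # pos is the index of the P1' residue
        return (
            pos + 2 < len(aa)
            and aa[pos] in params.p1_prime
            and aa[pos + 1] == "L"
            and aa[pos + 2] in params.p3_prime
        )

    start = asn + 1
    best_p = None
    for p in range(asn + params.span_min, asn + params.span_max + 1):
        if p + 3 >= len(aa):
            break
        if aa[p] == "D" and tail_matches(p + 1):
            best_p = p
    if best_p is not None:
        return start, best_p + 1, "plp_with_asp"
    for q in range(start + params.span_min, start + params.span_max + 1):
        if q + 2 >= len(aa):
            break
        if tail_matches(q):
            return start, q, "asp_lacking"
    return None


def find_precursors(
    translations: list[OrfTranslation], params: MiningParams | None = None
) -> list[PrecursorCandidate]:
    """Scan open reading segments for PawL1-like precursor architecture.

    A candidate needs (i) a hydrophobic N-terminal stretch (ER signal),
    (ii) an Asn in the allowed position window, (iii) a 5-12 residue span
    ending at an AEP-processable Asp (or, failing that, delimited by the
    trailing-tail pattern alone: 'asp_lacking'), and (iv) a Cys-rich
    downstream region evidencing the albumin domain. An empty result is a
    valid outcome. Candidates are sorted by combined score, descending.
    """
    if params is None:
        params = MiningParams()
    out: list[PrecursorCandidate] = []
    for tr in translations:
        aa = tr.aa_seq
        score = er_signal_score(aa, params)
        if score < params.er_hydropathy_threshold:
            continue
        hi = min(params.asn_max, len(aa) - 1)
        for asn in range(params.asn_min, hi + 1):
            if aa[asn] != "N":
                continue
            span = _find_span(aa, asn, params)
            if span is None:
                continue
            s, e, cls = span
            tail = aa[e : e + 4]
            if len(tail) < 4:
                continue
            alb_region = aa[e + 4 : e + 4 + params.cys_window]
            n_cys = alb_region.count("C")
            if n_cys < params.min_cys:
                continue
            out.append(
                PrecursorCandidate(
                    source=tr,
                    er_signal_score=score,
                    asn_position=asn,
                    plp_span=(s, e),
                    tail=tail,
                    albumin_score=float(n_cys),
                    candidate_class=cls,
                )
            )
    out.sort(key=lambda c: (-c.combined_score, c.source.transcript_id, c.asn_position))
    return out


def extract_plp(candidate: PrecursorCandidate) -> CyclicPeptide:
    """The encoded cyclic peptide of a Asp-terminated candidate."""
    if candidate.candidate_class != "plp_with_asp":
        raise ValueError(
            f"cannot extract a PLP from a {candidate.candidate_class!r} candidate: "
            "the span does not end in the proto-C-terminal Asp"
        )
    seq = candidate.plp_seq
    if not seq.endswith("D"):
        raise ValueError(f"span {seq!r} does not end in Asp")
    return CyclicPeptide(
        encoded_seq=seq,
        name=candidate.source.transcript_id,
        gene=f"{candidate.source.strand}frame{candidate.source.frame}",
        species="",
    )


def predicted_mass_list(candidates: list[PrecursorCandidate]) -> pd.DataFrame:
    """Target table for mass-directed LC-MS/MS: one row per unique macrocycle."""
    rows = {}
    for c in candidates:
        if c.candidate_class != "plp_with_asp":
            continue
        seq = c.plp_seq
        canon = canonical_rotation(seq)
        if canon in rows:
            continue
        m = cyclic_monoisotopic_mass(seq)
        rows[canon] = {
            "encoded_seq": seq,
            "cyclic_mass": round_mass(m),
            "mh_mz": round_mass(mz_from_mass(m, 1)),
        }
    return pd.DataFrame(list(rows.values()), columns=["encoded_seq", "cyclic_mass", "mh_mz"])


def candidates_table(candidates: list[PrecursorCandidate]) -> pd.DataFrame:
    """Flat TSV-ready view of mining output."""
    return pd.DataFrame(
        [
            {
                "transcript_id": c.source.transcript_id,
                "strand": c.source.strand,
                "frame": c.source.frame,
                "asn_position": c.asn_position,
                "plp_seq": c.plp_seq,
                "tail": c.tail,
                "class": c.candidate_class,
                "er_signal_score": round(c.er_signal_score, 3),
                "albumin_score": c.albumin_score,
            }
            for c in candidates
        ],
        columns=[
            "transcript_id", "strand", "frame", "asn_position", "plp_seq",
            "tail", "class", "er_signal_score", "albumin_score",
        ],
    )
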