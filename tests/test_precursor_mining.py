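"""Six-frame translation and the PawL1 precursor scanner."""

import numpy as np
import pandas as pd
import pytest

from Bio.Seq import Seq

from plpmine.precursor_mining import (
    MiningParams,
    TranscriptRecord,
    extract_plp,
    find_precursors,
    predicted_mass_list,
    six_frame_translate,
)
from plpmine.synthetic_data import SimulationParams, build_precursor, random_plp


def _reverse_translate_simple(protein):
    # fixed codon per residue; enough for round-trip construction
    from Bio.Data.CodonTable import standard_dna_table

    table = {}
    for codon, aa in sorted(standard_dna_table.forward_table.items()):
        table.setdefault(aa, codon)
    return "".join(table[aa] for aa in protein)


def test_six_frame_round_trip():
    protein = "M" + "L" * 19 + "STEQ" * 5 + "N" + "GYVFPD" + "GLDN" + "A" * 60
    nt = _reverse_translate_simple(protein)
    segs = six_frame_translate(TranscriptRecord("t", nt))
    plus = [s for s in segs if s.strand == "+" and "NGYVFPDGLDN" in s.aa_seq]
    assert len(plus) == 1
    assert plus[0].aa_seq == protein


def test_six_frame_reverse_complement_symmetry():
    protein = "M" + "V" * 19 + "STEQ" * 5 + "N" + "GYVFPD" + "GLDN" + "A" * 60
    nt = _reverse_translate_simple(protein)
    rc = str(Seq(nt).reverse_complement())
    segs = six_frame_translate(TranscriptRecord("t", rc))
    minus = [s for s in segs if s.strand == "-" and "NGYVFPDGLDN" in s.aa_seq]
    assert len(minus) == 1
    # coordinates are reported on the + strand of the (rev-comp) input
    assert 0 <= minus[0].nt_start < minus[0].nt_end <= len(rc)


def test_six_frame_all_stops_is_empty():
    # frame 1 is wall-to-wall stops; (other frames read poly-Asn, which is
    # a legitimate open segment)
    segs = six_frame_translate(TranscriptRecord("t", "TAA" * 50))
    assert [s for s in segs if s.strand == "+" and s.frame == 1] == []


def test_transcript_rejects_non_nucleotides():
    with pytest.raises(ValueError, match="non-nucleotide"):
        TranscriptRecord("t", "ACGTQ" * 20)


def test_find_precursors_round_trip(rng):
    params = SimulationParams(seed=9)
    _, transcript, truth = build_precursor("GYVFPD", rng, params, "tx1")
    segs = six_frame_translate(TranscriptRecord("tx1", transcript))
    cands = find_precursors(segs)
    with_asp = [c for c in cands if c.candidate_class == "plp_with_asp"]
    assert len(with_asp) == 1
    cand = with_asp[0]
    assert cand.plp_seq == "GYVFPD"
    assert cand.tail == "GLDN"
    assert cand.source.aa_seq[cand.asn_position] == "N"
    pep = extract_plp(cand)
    assert pep.encoded_seq == "GYVFPD"


def test_find_precursors_asp_mutant_classed_asp_lacking(rng):
    params = SimulationParams(seed=9)
    protein, transcript, truth = build_precursor("GYVFPD", rng, params, "tx1")
    mutated = protein.replace("NGYVFPDGLDN", "NGYVFPGGLDN")
    nt = _reverse_translate_simple(mutated)
    cands = find_precursors(six_frame_translate(TranscriptRecord("tx2", nt)))
    assert len(cands) == 1
    assert cands[0].candidate_class == "asp_lacking"
    assert cands[0].plp_seq == "GYVFPG"
    with pytest.raises(ValueError, match="asp_lacking"):
        extract_plp(cands[0])


def test_internal_asp_span_uses_last_asp(rng):
    """Internal Asp must not truncate the peptide span."""
    params = SimulationParams(seed=9)
    _, transcript, _ = build_precursor("KYGPPVDFD", rng, params, "tx1")
    cands = find_precursors(six_frame_translate(TranscriptRecord("tx1", transcript)))
    with_asp = [c for c in cands if c.candidate_class == "plp_with_asp"]
    assert [c.plp_seq for c in with_asp] == ["KYGPPVDFD"]


def test_chance_motif_without_albumin_rejected():
    # plausible N..D GL motif but no downstream Cys-rich region
    protein = "M" + "L" * 19 + "STEQ" * 5 + "N" + "GYVFPD" + "GLDN" + "A" * 130
    nt = _reverse_translate_simple(protein)
    cands = find_precursors(six_frame_translate(TranscriptRecord("t", nt)))
    assert cands == []


def test_specificity_on_random_transcripts():
    """Candidate rate on unplanted transcripts stays below 1 per 1e4."""
    rng = np.random.default_rng(17)
    n = 10_000
    hits = 0
    for i in range(n):
        nt = "".join(rng.choice(list("ACGT"), size=600))
        segs = six_frame_translate(TranscriptRecord(f"r{i}", nt))
        hits += bool(find_precursors(segs))
    assert hits / n < 1e-4


def test_recall_on_synthetic_dataset(small_dataset):
    import plpmine.precursor_mining as pmn

    truth = pd.read_csv(small_dataset["truth"], sep="\t")
    transcripts = pmn.read_fasta(small_dataset["fasta"])
    segs = []
    for t in transcripts:
        segs.extend(six_frame_translate(t))
    cands = find_precursors(segs)
    mined = {
        (c.source.transcript_id, c.plp_seq)
        for c in cands
        if c.candidate_class == "plp_with_asp"
    }
    for _, row in truth.iterrows():
        assert (row.transcript_id, row.plp_seq) in mined
    # exact span boundaries against the generator truth table
    by_tid = {c.source.transcript_id: c for c in cands if c.candidate_class == "plp_with_asp"}
    for _, row in truth.iterrows():
        c = by_tid[row.transcript_id]
        assert (c.plp_span[0], c.plp_span[1]) == (row.span_start, row.span_end)
        assert c.asn_position == row.asn_position


def test_every_extracted_plp_flanked_correctly(small_dataset):
    import plpmine.precursor_mining as pmn

    transcripts = pmn.read_fasta(small_dataset["fasta"])
    segs = []
    for t in transcripts:
        segs.extend(six_frame_translate(t))
    for c in find_precursors(segs):
        if c.candidate_class != "plp_with_asp":
            continue
        pep = extract_plp(c)
        assert pep.encoded_seq.endswith("D")
        assert c.source.aa_seq[c.asn_position] == "N"
        assert c.plp_span[0] == c.asn_position + 1


def test_predicted_mass_list_dedupes_rotations(rng):
    params = SimulationParams(seed=9)
    segs = []
    for i, plp in enumerate(["GYVFPD", "YVFPDG"]):  # same macrocycle
        _, transcript, _ = build_precursor(plp, rng, params, f"t{i}")
        segs.extend(six_frame_translate(TranscriptRecord(f"t{i}", transcript)))
    cands = find_precursors(segs)
    table = predicted_mass_list(cands)
    assert len(table) == 1
    assert table.iloc[0]["cyclic_mass"] == pytest.approx(678.301, abs=1e-3)
    assert table.iloc[0]["mh_mz"] == pytest.approx(679.309, abs=1e-3)


def test_predicted_mass_list_empty():
    assert len(predicted_mass_list([])) == 0
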