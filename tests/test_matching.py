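"""Spectrum matching, series constraints, uniqueness confirmation."""

import numpy as np
import pytest

from plpmine.peptide_core import CyclicPeptide, canonical_rotation, mz_from_mass, cyclic_monoisotopic_mass
from plpmine.matching import (
    Spectrum,
    confirm_by_uniqueness,
    distinct_cyclic_arrangements,
    match_spectrum,
    precursor_screen,
    rank_candidates,
    read_mgf,
    resolve_isobaric,
)
from plpmine.synthetic_data import (
    SimulationParams,
    favored_openings,
    mass_matched_decoys,
    noiseless_spectrum,
    series_spectrum,
    simulate_spectrum,
    write_mgf,
)


def pep(seq):
    return CyclicPeptide(encoded_seq=seq)


# ---------------------------------------------------------------- MGF I/O


def test_mgf_round_trip(tmp_path, rng):
    params = SimulationParams(seed=2)
    spectra = [
        simulate_spectrum("GYVFPD", params, rng, spectrum_id="a"),
        simulate_spectrum("AIIPGLID", params, rng, spectrum_id="b"),
    ]
    path = tmp_path / "two.mgf"
    write_mgf(spectra, path)
    back = read_mgf(path)
    assert [s.id for s in back] == ["a", "b"]
    for orig, rt in zip(spectra, back):
        assert rt.precursor_charge == 1
        np.testing.assert_allclose(rt.peaks_mz, np.sort(orig.peaks_mz), atol=1e-5)


def test_mgf_missing_charge_defaults_to_one(tmp_path):
    path = tmp_path / "nocharge.mgf"
    path.write_text(
        "BEGIN IONS\nTITLE=x\nPEPMASS=679.30860\n213.08700 1.0\nEND IONS\n"
    )
    (sp,) = read_mgf(path)
    assert sp.precursor_charge == 1
    assert sp.id == "x"


def test_mgf_malformed_block_names_index(tmp_path):
    path = tmp_path / "bad.mgf"
    path.write_text("BEGIN IONS\nTITLE=x\nPEPMASS=oops\n100 1\nEND IONS\n")
    with pytest.raises(ValueError, match="block at index 0"):
        read_mgf(path)


# ------------------------------------------------------- precursor screen


def test_precursor_screen_pairs_within_tolerance():
    sp = Spectrum("s", 679.309, 1, np.array([213.087]), np.array([1.0]))
    pairs = precursor_screen([sp], [pep("GYVFPD")], tol=0.02)
    assert len(pairs) == 1
    assert precursor_screen([sp], [pep("GYVFPD")], tol=0.001) == [] or abs(
        sp.observed_mh - mz_from_mass(cyclic_monoisotopic_mass("GYVFPD"), 1)
    ) <= 0.001


def test_precursor_screen_jittered_out_of_tight_tolerance():
    sp = Spectrum("s", 679.315, 1, np.array([213.087]), np.array([1.0]))
    assert precursor_screen([sp], [pep("GYVFPD")], tol=0.001) == []
    assert len(precursor_screen([sp], [pep("GYVFPD")], tol=0.02)) == 1


def test_precursor_screen_keeps_isobaric_candidates():
    sp = Spectrum("s", 679.309, 1, np.array([213.087]), np.array([1.0]))
    pairs = precursor_screen([sp], [pep("GYVFPD"), pep("GYFVPD")], tol=0.02)
    assert len(pairs) == 2


def test_precursor_screen_charge_two():
    mh2 = mz_from_mass(cyclic_monoisotopic_mass("GYVFPD"), 2)
    sp = Spectrum("s", mh2, 2, np.array([213.087]), np.array([1.0]))
    assert len(precursor_screen([sp], [pep("GYVFPD")], tol=0.02)) == 1


# ---------------------------------------------------------- match_spectrum


def test_self_match_full_coverage():
    sp = noiseless_spectrum("GYVFPD", min_b=1)
    rep = match_spectrum(sp, pep("GYVFPD"), 0.01)
    assert rep.b_ion_fraction == 1.0
    assert rep.adjacency_coverage == 1.0
    assert rep.mh_matched


def test_match_rotation_invariant():
    sp = noiseless_spectrum("GYVFPD", min_b=1)
    reports = [
        match_spectrum(sp, pep("GYVFPD"[i:] + "GYVFPD"[:i]), 0.01) for i in range(6)
    ]
    assert len({r.b_ion_fraction for r in reports}) == 1
    assert len({r.adjacency_coverage for r in reports}) == 1


def test_shuffled_composition_scores_lower():
    sp = noiseless_spectrum("GYVFPD", min_b=1)
    true_rep = match_spectrum(sp, pep("GYVFPD"), 0.005)
    shuf_rep = match_spectrum(sp, pep("GVYFPD"), 0.005)
    assert shuf_rep.matched_b_count < true_rep.matched_b_count


def test_matched_count_monotone_in_tolerance(rng):
    params = SimulationParams(seed=4)
    sp = simulate_spectrum("AIIPGLID", params, rng, spectrum_id="m")
    counts = [
        match_spectrum(sp, pep("AIIPGLID"), tol).matched_ion_count
        for tol in (0.001, 0.005, 0.01, 0.02, 0.05)
    ]
    assert counts == sorted(counts)


def test_one_peak_serves_one_ion():
    # two theoretical ions near one observed peak: only one may claim it
    sp = Spectrum("s", 679.309, 1, np.array([213.087]), np.array([5.0]))
    rep = match_spectrum(sp, pep("GYVFPD"), 0.5)
    assert rep.matched_ion_count == 1


# ------------------------------------------------- series and constraints


def test_worked_example_series_and_constraints():
    """The three published series of the GYVFPD spectrum and its rendering."""
    sp = noiseless_spectrum("GYVFPD", min_b=2)
    rep = match_spectrum(sp, pep("GYVFPD"), 0.01, min_n=1)
    ranges = {s.label_range() for s in rep.series}
    assert "b2PF-b5PF" in ranges
    assert "b2FV-b5FV" in ranges  # contains the published b3FV-b5FV
    assert "b2GD-b5GD" in ranges  # contains the published b2GD-b4GD
    assert "[P,D]-G-Y-V-F" in rep.constraints()


def test_worked_example_series_nine_residues():
    sp = noiseless_spectrum("KYGPPVDFD", min_b=2)
    rep = match_spectrum(sp, pep("KYGPPVDFD"), 0.01, min_n=1)
    ranges = {s.label_range() for s in rep.series}
    assert "b2PG-b8PG" in ranges  # contains the published b2PG-b7PG
    assert "b3GY-b8GY" in {r for r in ranges} or "b2GY-b8GY" in ranges
    constraints = rep.constraints()
    assert any(c.endswith("P-V-D-F-D-K-Y") for c in constraints)


def test_single_b2_renders_bracket_only():
    ions_mz = []
    from plpmine.fragmentation import enumerate_fragments

    ion = {f.label: f for f in enumerate_fragments("GYVFPD")}["b2PF"]
    sp = Spectrum("s", 679.309, 1, np.array([ion.mz]), np.array([1.0]))
    rep = match_spectrum(sp, pep("GYVFPD"), 0.005)
    assert rep.constraints() == ["[P,D]"]


# ------------------------------------------------------------ confirmation


def test_exhaustive_uniqueness_on_worked_example():
    # the three published ring openings of the GYVFPD spectrum (P, F, G)
    sp = series_spectrum("GYVFPD", (5, 4, 1))
    confirmed, margin = confirm_by_uniqueness(sp, pep("GYVFPD"), 0.005, "exhaustive")
    assert confirmed
    assert margin is not None and margin >= 0


def test_reversed_cycle_is_isospectral_but_not_confirmed_structurally():
    """A cycle and its reversal share the b-ion m/z multiset exactly; only
    series structure separates them."""
    from plpmine.fragmentation import enumerate_fragments

    seq = "GYVFPD"
    rev = seq[::-1]
    mzs = lambda s: sorted(
        round(f.mz, 6) for f in enumerate_fragments(s) if f.n < len(s)
    )
    assert mzs(seq) == mzs(rev)
    sp = series_spectrum(seq, (5, 4, 1))
    true_rep = match_spectrum(sp, pep(seq), 0.005, min_n=2)
    rev_rep = match_spectrum(sp, pep(rev), 0.005, min_n=2)
    longest = lambda r: max((s.length for s in r.series), default=0)
    assert longest(rev_rep) < longest(true_rep)


def test_exhaustive_arrangement_count():
    # 6 distinct residues: 5! = 120 cycles up to rotation
    assert len(distinct_cyclic_arrangements("GYVFPD")) == 120


def test_exhaustive_refused_for_large_rings():
    sp = noiseless_spectrum("FVETTAGLLD", min_b=1)  # N = 10
    with pytest.raises(ValueError, match="sampled"):
        confirm_by_uniqueness(sp, pep("FVETTAGLLD"), 0.005, "exhaustive")


def test_sampled_mode_confirms_large_ring():
    sp = series_spectrum("FVETTAGLLD", favored_openings("FVETTAGLLD", 4))
    confirmed, margin = confirm_by_uniqueness(
        sp, pep("FVETTAGLLD"), 0.005, "sampled",
        rng=np.random.default_rng(0), k=2000,
    )
    assert confirmed


def test_single_series_does_not_confirm():
    from plpmine.fragmentation import enumerate_fragments

    ions = {f.label: f for f in enumerate_fragments("GYVFPD")}
    sp = Spectrum("s", 679.309, 1, np.array([ions["b2PF"].mz]), np.array([1.0]))
    confirmed, _ = confirm_by_uniqueness(sp, pep("GYVFPD"), 0.005, "exhaustive")
    assert not confirmed


def test_constraint_mode_transcript_agreement():
    sp = noiseless_spectrum("GYVFPD", min_b=2)
    confirmed, _ = confirm_by_uniqueness(
        sp, pep("GYVFPD"), 0.005, "constraint", candidate_set=[pep("GYVFPD")]
    )
    assert confirmed
    # a rival candidate that also fits all constraints blocks confirmation
    confirmed2, _ = confirm_by_uniqueness(
        sp, pep("GYVFPD"), 0.5, "constraint",
        candidate_set=[pep("GYVFPD"), pep("GYVFPE")],
    )
    # GYVFPE does not fit the series of GYVFPD at sane tolerance; sanity only
    assert isinstance(confirmed2, bool)


def test_catalog_noiseless_confirmation(catalog):
    """Noiseless series evidence pins down every small catalog peptide up to
    the retro ambiguity: the reversed cycle shares the full b-ion m/z
    multiset and, for rings without a favored opening, cannot be excluded
    by mass evidence at all."""
    from plpmine.matching import uniqueness_blockers

    unconfirmed = {}
    for p in catalog.unique_peptides:
        if len(p) > 8:  # keep the exhaustive scan desk-scale in one test
            continue
        sp = series_spectrum(p.encoded_seq, favored_openings(p.encoded_seq, 3))
        confirmed, margin = confirm_by_uniqueness(sp, p, 0.001, "exhaustive")
        if not confirmed:
            blockers = uniqueness_blockers(sp, p, 0.001)
            iso = p.encoded_seq.replace("I", "L")
            retro = canonical_rotation(iso[::-1])
            assert blockers == [retro], (p.encoded_seq, blockers)
            unconfirmed[p.encoded_seq] = blockers
    # retro-blocked cases are rare exceptions, not the rule
    assert len(unconfirmed) <= 1, unconfirmed


# --------------------------------------------------------------- ranking


def test_true_candidate_ranks_first_noiseless(rng):
    seq = "AIIPGLID"
    sp = noiseless_spectrum(seq, min_b=1)
    decoys = mass_matched_decoys(seq, 9, rng)
    ranking = rank_candidates(sp, [pep(seq), *decoys], 0.005)
    assert canonical_rotation(ranking[0][0].encoded_seq) == canonical_rotation(seq)


def test_rank_ties_deterministic_for_rotations():
    # rotations of one macrocycle are fully tied; the outcome must be
    # deterministic (same canonical top) regardless of input order
    sp = noiseless_spectrum("GYVFPD", min_b=1)
    a = rank_candidates(sp, [pep("GYVFPD"), pep("GYFVPD")], 0.005)
    b = rank_candidates(sp, [pep("DGYVFP"), pep("GYFVPD")], 0.005)
    assert canonical_rotation(a[0][0].encoded_seq) == canonical_rotation(b[0][0].encoded_seq) == "DGYVFP"


def test_rank_empty_candidates():
    sp = noiseless_spectrum("GYVFPD", min_b=1)
    assert rank_candidates(sp, [], 0.005) == []


# -------------------------------------------------------------- isobarics


def test_resolve_isobaric_unique():
    resolved = resolve_isobaric(
        "A[I/L][I/L]PG[I/L][I/L]D", [pep("AIIPGLID"), pep("GYVFPD")]
    )
    assert resolved.encoded_seq == "AIIPGLID"


def test_resolve_isobaric_errors():
    with pytest.raises(ValueError, match="no transcript support"):
        resolve_isobaric("A[I/L]D", [])
    with pytest.raises(ValueError, match="ambiguous"):
        resolve_isobaric(
            "A[I/L][I/L]PG[I/L][I/L]D", [pep("AIIPGLID"), pep("ALIPGILD")]
        )
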