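"""Spectrum-to-candidate matching and series-based sequence confirmation.

A cyclic peptide cannot be read off a single MS/MS ladder: every ring
opening seeds its own b-ion series, and any one series determines the
residue order only partially. The confirmation logic here mirrors manual
cyclic-peptide sequencing: extract maximal contiguous b-ion series per
ring opening, turn each into a sequence constraint of the form
``[P,D]-G-Y-V-F`` (leading residues in unknown order, then an ordered
walk, with [M+H]+ closing the ring), and accept a transcript-predicted
candidate only when the constraints single it out.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pyteomics import mgf as _mgf

from .peptide_core import (
    PROTON_MASS,
    RESIDUE_MASSES,
    CyclicPeptide,
    canonical_rotation,
    cyclic_monoisotopic_mass,
    mz_from_mass,
    validate_sequence,
)
from .fragmentation import (
    FragmentIon,
    RingOpening,
    theoretical_b_ion_set,
)

#: Absolute fragment m/z tolerances by instrument (Da).
INSTRUMENT_TOLERANCES = {"qtof": 0.02, "orbitrap": 0.01}


@dataclass
class Spectrum:
    """A centroided MS/MS peak list with its precursor."""

    id: str
    precursor_mz: float
    precursor_charge: int
    peaks_mz: np.ndarray
    peaks_intensity: np.ndarray
    instrument: str = "qtof"

    def __post_init__(self) -> None:
        self.peaks_mz = np.asarray(self.peaks_mz, dtype=float)
        self.peaks_intensity = np.asarray(self.peaks_intensity, dtype=float)
        if self.peaks_mz.shape != self.peaks_intensity.shape:
            raise ValueError(f"{self.id}: peak m/z and intensity lengths differ")
        if self.precursor_charge < 1:
            raise ValueError(f"{self.id}: precursor charge must be >= 1")
        if np.any(self.peaks_intensity < 0):
            raise ValueError(f"{self.id}: negative peak intensity")
        order = np.argsort(self.peaks_mz, kind="stable")
        self.peaks_mz = self.peaks_mz[order]
        self.peaks_intensity = self.peaks_intensity[order]

    @property
    def observed_mh(self) -> float:
        """Observed precursor expressed as singly protonated [M+H]+."""
        z = self.precursor_charge
        return self.precursor_mz * z - (z - 1) * PROTON_MASS

    def relative_intensity(self) -> np.ndarray:
        top = self.peaks_intensity.max() if self.peaks_intensity.size else 1.0
        return self.peaks_intensity / (top if top > 0 else 1.0)


@dataclass(frozen=True)
class PeakMatch:
    ion: FragmentIon
    observed_mz: float
    observed_intensity: float

    @property
    def error(self) -> float:
        return self.observed_mz - self.ion.mz


@dataclass(frozen=True)
class SeriesEvidence:
    """A maximal contiguous run of matched b_n ions from one ring opening."""

    opening: RingOpening
    n_start: int
    n_end: int
    closed_by_mh: bool = False

    @property
    def length(self) -> int:
        return self.n_end - self.n_start + 1

    def label_range(self) -> str:
        from .fragmentation import ion_label

        first = ion_label("b", self.n_start, self.opening)
        last = ion_label("b", self.n_end, self.opening)
        return f"{first}-{last}" if first != last else first

    def bracket(self) -> str:
        """Leading residues whose internal order the series does not fix."""
        return self.opening.linearized[: self.n_start]

    def ordered(self) -> str:
        """Residues identified one-by-one by consecutive b-ion mass steps."""
        lin = self.opening.linearized
        tail = lin[self.n_start : self.n_end]
        if self.closed_by_mh and self.n_end == len(lin) - 1:
            tail += lin[-1]
        return tail


@dataclass
class MatchReport:
    candidate: CyclicPeptide
    matches: list[PeakMatch]
    series: list[SeriesEvidence]
    matched_ion_count: int
    matched_b_count: int
    b_ion_fraction: float
    adjacency_coverage: float
    matched_intensity: float
    mh_matched: bool
    confirmed: bool = False
    uniqueness_margin: float | None = None

    def constraints(self) -> list[str]:
        return render_constraints(self.series, self.mh_matched)


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF peak-list file into Spectrum objects.

    Blocks without a CHARGE line default to 1+. A malformed block raises
    a ValueError naming its 0-based index in the file.
    """
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        i = 0
        iterator = iter(reader)
        while True:
            try:
                try:
                    entry = next(iterator)
                except StopIteration:
                    break
                params = entry["params"]
                pepmass = params["pepmass"]
                prec_mz = float(pepmass[0] if isinstance(pepmass, tuple) else pepmass)
                charge_field = params.get("charge")
                charge = int(charge_field[0]) if charge_field else 1
                sid = str(params.get("title", f"spectrum_{i}"))
                instrument = str(params.get("instrument", "qtof")).lower()
                spectra.append(
                    Spectrum(
                        id=sid,
                        precursor_mz=prec_mz,
                        precursor_charge=charge,
                        peaks_mz=entry["m/z array"],
                        peaks_intensity=entry["intensity array"],
                        instrument=instrument if instrument in INSTRUMENT_TOLERANCES else "qtof",
                    )
                )
            except (KeyError, TypeError, ValueError, IndexError) as exc:
                raise ValueError(f"malformed MGF block at index {i}: {exc}") from exc
            i += 1
    return spectra


def precursor_screen(
    spectra: list[Spectrum],
    candidates: list[CyclicPeptide],
    tol: float = INSTRUMENT_TOLERANCES["qtof"],
) -> list[tuple[Spectrum, CyclicPeptide]]:
    """All (spectrum, candidate) pairs whose [M+H]+ agree within ``tol`` Da.

    Multiply-charged precursors are converted to their [M+H]+ equivalent
    before comparison. Isobaric candidates are all retained: ambiguity is
    resolved downstream by fragment evidence, not here.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    pairs = []
    for sp in spectra:
        for cand in candidates:
            predicted = mz_from_mass(cand.cyclic_mass, 1)
            if abs(sp.observed_mh - predicted) <= tol:
                pairs.append((sp, cand))
    return pairs


def _assign_peaks(
    ions: list[FragmentIon], spectrum: Spectrum, tol: float
) -> list[PeakMatch]:
    """One-to-one nearest-error assignment of observed peaks to theoretical ions.

    Each observed peak annotates at most one theoretical ion so a single
    noise peak cannot inflate coverage; among competing assignments the
    smallest |error| wins, ties broken toward higher observed intensity.
    """
    mz = spectrum.peaks_mz
    inten = spectrum.peaks_intensity
    pool: list[tuple[float, float, int, int]] = []
    for ti, ion in enumerate(ions):
        lo = np.searchsorted(mz, ion.mz - tol, side="left")
        hi = np.searchsorted(mz, ion.mz + tol, side="right")
        for pi in range(lo, hi):
            pool.append((abs(mz[pi] - ion.mz), -inten[pi], ti, pi))
    pool.sort()
    used_t: set[int] = set()
    used_p: set[int] = set()
    matches: list[PeakMatch] = []
    for err, neg_i, ti, pi in pool:
        if ti in used_t or pi in used_p:
            continue
        used_t.add(ti)
        used_p.add(pi)
        matches.append(PeakMatch(ions[ti], float(mz[pi]), float(inten[pi])))
    matches.sort(key=lambda m: m.ion.mz)
    return matches


def _extract_series(
    seq: str, matches: list[PeakMatch], mh_matched: bool
) -> list[SeriesEvidence]:
    n_res = len(seq)
    matched_by_opening: dict[int, set[int]] = {}
    for m in matches:
        op = m.ion.opening
        if m.ion.ion_type == "b" and op is not None:
            matched_by_opening.setdefault(op.opening_index, set()).add(m.ion.n)
    series: list[SeriesEvidence] = []
    for j in sorted(matched_by_opening):
        ns = matched_by_opening[j]
        op = RingOpening(seq, j)
        for n in sorted(ns):
            if n - 1 in ns:
                continue  # not the start of a maximal run
            end = n
            while end + 1 in ns:
                end += 1
            closed = mh_matched and end == n_res - 1
            series.append(SeriesEvidence(op, n, end, closed))
    return series


def _adjacency_coverage(seq: str, matches: list[PeakMatch], mh_matched: bool) -> float:
    """Fraction of the N backbone bonds whose cleavage is evidenced.

    A bond is evidenced when two consecutive matched ions of one opening
    (treating a matched [M+H]+ as b_N for every opening) differ by exactly
    that one residue: the pair (b_n, b_{n+1}) localizes the cleavage
    between linearized positions n and n+1.
    """
    n_res = len(seq)
    matched_by_opening: dict[int, set[int]] = {}
    for m in matches:
        op = m.ion.opening
        if m.ion.ion_type == "b" and op is not None:
            matched_by_opening.setdefault(op.opening_index, set()).add(m.ion.n)
    evidenced: set[int] = set()
    for j, ns in matched_by_opening.items():
        o = j - 1  # 0-based opening offset in encoded coordinates
        full = set(ns)
        if mh_matched:
            full.add(n_res)  # [M+H]+ acts as b_N
        for n in ns:
            if n + 1 in full:
                evidenced.add((o + n - 1) % n_res)
    return len(evidenced) / n_res


def match_spectrum(
    spectrum: Spectrum,
    candidate: CyclicPeptide,
    tol: float | None = None,
    *,
    ions: list[FragmentIon] | None = None,
    min_n: int = 1,
) -> MatchReport:
    """Annotate ``spectrum`` against one cyclic candidate.

    The default theoretical space is the plain b-ion set over all ring
    openings plus [M+H]+; a richer set (a-ions, losses, immonium) can be
    passed via ``ions``.
    """
    if tol is None:
        tol = INSTRUMENT_TOLERANCES.get(spectrum.instrument, 0.02)
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    seq = candidate.encoded_seq
    if ions is None:
        ions = theoretical_b_ion_set(seq, min_n=min_n)
    matches = _assign_peaks(ions, spectrum, tol)
    mh_matched = any(m.ion.ion_type == "MH" for m in matches)
    series = _extract_series(seq, matches, mh_matched)
    n_res = len(seq)
    b_matches = [m for m in matches if m.ion.ion_type == "b"]
    total_b = sum(1 for i in ions if i.ion_type == "b")
    rel = spectrum.relative_intensity()
    top = spectrum.peaks_intensity.max() if spectrum.peaks_intensity.size else 1.0
    matched_rel = sum(m.observed_intensity for m in matches) / (top if top > 0 else 1.0)
    return MatchReport(
        candidate=candidate,
        matches=matches,
        series=series,
        matched_ion_count=len(matches),
        matched_b_count=len(b_matches),
        b_ion_fraction=(len(b_matches) / total_b) if total_b else 0.0,
        adjacency_coverage=_adjacency_coverage(seq, matches, mh_matched),
        matched_intensity=matched_rel,
        mh_matched=mh_matched,
    )


def render_constraints(series: list[SeriesEvidence], mh_matched: bool) -> list[str]:
    """Render each b-ion series as a bracketed sequence constraint.

    The first matched b_n fixes only the *composition* of its n residues
    (square brackets); every further consecutive b-step identifies one
    ordered residue; a matched [M+H]+ closes the ring by supplying the
    final residue.
    """
    out = []
    for s in series:
        bracket = s.bracket()
        ordered = s.ordered()
        if len(bracket) == 1:
            head = bracket
        else:
            head = "[" + ",".join(bracket) + "]"
        out.append("-".join([head, *ordered]) if ordered else head)
    return out


def _series_consistent(candidate_seq: str, bracket: str, ordered: str) -> bool:
    """Does some rotation of the candidate cycle satisfy bracket+ordered?"""
    n = len(candidate_seq)
    need = len(bracket) + len(ordered)
    if need > n:
        return False
    doubled = candidate_seq * 2
    want_bracket = sorted(bracket)
    for r in range(n):
        window = doubled[r : r + need]
        if sorted(window[: len(bracket)]) == want_bracket and window[len(bracket):] == ordered:
            return True
    return False


def candidate_satisfies(candidate_seq: str, report: MatchReport) -> bool:
    """True if every rendered series constraint fits the candidate cycle."""
    return all(
        _series_consistent(candidate_seq, s.bracket(), s.ordered())
        for s in report.series
    )


def _cyclic_window_mz(seq: str, min_n: int = 1) -> np.ndarray:
    """m/z of all plain b-ions (contiguous cyclic windows + proton) plus [M+H]+."""
    masses = np.array([RESIDUE_MASSES[c] for c in seq])
    n = len(seq)
    doubled = np.concatenate([masses, masses])
    csum = np.concatenate([[0.0], np.cumsum(doubled)])
    vals = [csum[o + ln] - csum[o] + PROTON_MASS
            for o in range(n) for ln in range(min_n, n)]
    vals.append(masses.sum() + PROTON_MASS)  # [M+H]+
    return np.unique(np.round(vals, 6))


def _fast_score(seq: str, mz_sorted: np.ndarray, tol: float, min_n: int = 1) -> int:
    """Number of distinct theoretical b/[M+H]+ m/z values with an observed peak in tol."""
    theo = _cyclic_window_mz(seq, min_n)
    lo = np.searchsorted(mz_sorted, theo - tol, side="left")
    hi = np.searchsorted(mz_sorted, theo + tol, side="right")
    return int(np.sum(hi > lo))


def distinct_cyclic_arrangements(seq: str) -> list[str]:
    """All distinct head-to-tail cycles of the residue multiset of ``seq``.

    Cycles are returned as canonical rotations; rotations are identified,
    reversals are not (directionality is chemically meaningful).
    """
    residues = sorted(seq)
    anchor = residues[0]
    rest = residues[1:]
    seen: set[str] = set()
    for perm in set(itertools.permutations(rest)):
        seen.add(canonical_rotation(anchor + "".join(perm)))
    return sorted(seen)


EXHAUSTIVE_MAX_N = 9
SAMPLED_ARRANGEMENTS = 50_000


def confirm_by_uniqueness(
    spectrum: Spectrum,
    candidate: CyclicPeptide,
    tol: float,
    mode: str = "exhaustive",
    *,
    candidate_set: list[CyclicPeptide] | None = None,
    rng: np.random.Generator | None = None,
    k: int = SAMPLED_ARRANGEMENTS,
    min_n: int = 1,
) -> tuple[bool, float | None]:
    """Decide whether the spectrum pins down the candidate cycle uniquely.

    mode "constraint": every extracted series constraint must fit the
    candidate and no *other* member of the transcript-derived
    ``candidate_set`` may fit them all — the transcript-agreement decision.

    mode "exhaustive" (N <= 9): score every distinct cyclic arrangement of
    the candidate's residue multiset; confirmed iff the candidate is
    strictly top. The primary score is the matched-ion count; arrangements
    that tie on count (notably the reversed cycle, whose b-ion m/z multiset
    is *identical* to the candidate's) are separated by series structure:
    longest contiguous matched b-run, then ring-opening propensity
    plausibility. Returns (confirmed, margin) where margin = candidate
    matched count - best alternative matched count (0 when the decisive
    evidence was series structure rather than count).

    mode "sampled": like exhaustive but over ``k`` seeded random
    arrangements, for peptides too large to enumerate.
    """
    seq = candidate.encoded_seq
    n = len(seq)
    report = match_spectrum(spectrum, candidate, tol, min_n=min_n)
    if mode == "constraint":
        if candidate_set is None:
            candidate_set = [candidate]
        if not report.series or not candidate_satisfies(seq, report):
            return False, None
        own_canon = canonical_rotation(seq)
        rivals = [
            c for c in candidate_set
            if canonical_rotation(c.encoded_seq) != own_canon
            and candidate_satisfies(c.encoded_seq, report)
        ]
        return (len(rivals) == 0), None

    # MS cannot distinguish the isobaric residues Ile and Leu, so the
    # arrangement space is built over the isobaric-collapsed multiset
    # (I -> L); the I/L assignment is later settled from transcript data
    # (resolve_isobaric), not from the spectrum.
    iso = seq.replace("I", "L")
    if mode == "exhaustive":
        if n > EXHAUSTIVE_MAX_N:
            raise ValueError(
                f"exhaustive mode refused for N={n} > {EXHAUSTIVE_MAX_N}; "
                "use mode='sampled'"
            )
        arrangements = distinct_cyclic_arrangements(iso)
    elif mode == "sampled":
        if rng is None:
            rng = np.random.default_rng(0)
        residues = list(iso)
        seen = set()
        for _ in range(k):
            rng.shuffle(residues)
            seen.add(canonical_rotation("".join(residues)))
        seen.add(canonical_rotation(iso))
        arrangements = sorted(seen)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    seq = iso
    own_canon = canonical_rotation(seq)
    mz_sorted = spectrum.peaks_mz
    own_score = _fast_score(seq, mz_sorted, tol, min_n)
    best_other = -1
    tied: list[str] = []
    for arr in arrangements:
        if arr == own_canon:
            continue
        s = _fast_score(arr, mz_sorted, tol, min_n)
        if s > best_other:
            best_other = s
            tied = [arr]
        elif s == best_other:
            tied.append(arr)
    if best_other < 0:
        return True, float(own_score)
    margin = float(own_score - best_other)
    if best_other > own_score:
        return False, margin
    if best_other < own_score:
        return True, margin
    # Count ties (the reversed cycle always does): fall back to series
    # structure, which the count cannot see.
    own_key = _structural_key(seq, spectrum, tol, min_n)
    for arr in tied:
        if _structural_key(arr, spectrum, tol, min_n) >= own_key:
            return False, 0.0
    return True, 0.0


def _structural_key(seq: str, spectrum: Spectrum, tol: float, min_n: int) -> tuple:
    """(longest contiguous b-series, opening-propensity plausibility)."""
    rep = match_spectrum(spectrum, CyclicPeptide(encoded_seq=seq), tol, min_n=min_n)
    longest = max((s.length for s in rep.series), default=0)
    return (longest, round(_propensity_score(rep), 6))


def uniqueness_blockers(
    spectrum: Spectrum,
    candidate: CyclicPeptide,
    tol: float,
    *,
    min_n: int = 1,
) -> list[str]:
    """Arrangements (isobaric-collapsed, canonical) that tie or beat the candidate.

    An empty list means exhaustive uniqueness confirms the candidate. The
    classic irreducible blocker is the retro (reversed) cycle, whose b-ion
    m/z multiset is identical and which only series structure — sometimes —
    separates.
    """
    iso = candidate.encoded_seq.replace("I", "L")
    own_canon = canonical_rotation(iso)
    own_count = _fast_score(iso, spectrum.peaks_mz, tol, min_n)
    own_key = _structural_key(iso, spectrum, tol, min_n)
    blockers = []
    for arr in distinct_cyclic_arrangements(iso):
        if arr == own_canon:
            continue
        s = _fast_score(arr, spectrum.peaks_mz, tol, min_n)
        if s > own_count or (
            s == own_count and _structural_key(arr, spectrum, tol, min_n) >= own_key
        ):
            blockers.append(arr)
    return blockers


def resolve_isobaric(pattern: str, candidates: list[CyclicPeptide]) -> CyclicPeptide:
    """Resolve Ile/Leu wildcards against transcript-derived candidates.

    ``pattern`` is an encoded-order sequence where MS-indistinguishable
    positions are written ``[I/L]``; exactly one candidate must survive.
    """
    tokens: list[frozenset[str]] = []
    i = 0
    while i < len(pattern):
        if pattern.startswith("[I/L]", i) or pattern.startswith("[L/I]", i):
            tokens.append(frozenset("IL"))
            i += 5
        elif pattern[i] in RESIDUE_MASSES:
            tokens.append(frozenset(pattern[i]))
            i += 1
        else:
            raise ValueError(f"unparseable token at position {i} in {pattern!r}")
    survivors = {}
    for cand in candidates:
        s = cand.encoded_seq
        if len(s) == len(tokens) and all(c in t for c, t in zip(s, tokens)):
            survivors[s] = cand
    if not survivors:
        raise ValueError(f"no transcript support for {pattern!r}")
    if len(survivors) > 1:
        raise ValueError(
            f"ambiguous: {sorted(survivors)} all match {pattern!r}"
        )
    return next(iter(survivors.values()))


# Ring-opening propensity priors used as a ranking tie-break: under CID,
# ring cleavage is favored N-terminal to Pro and at Ile/Leu-Asp bonds.
PRO_OPENING_WEIGHT = 5.0
ILD_OPENING_WEIGHT = 3.0


def _propensity_score(report: MatchReport) -> float:
    """Chemical plausibility of the matched series under the candidate.

    Sums, over matched plain b-ions, the prior weight of the ring opening
    they imply. Two candidates can explain the same peaks (a reversed
    cycle has an identical b-ion m/z multiset), but only one of them maps
    long series onto chemically favored openings.
    """
    score = 0.0
    for m in report.matches:
        op = m.ion.opening
        if m.ion.ion_type != "b" or op is None:
            continue
        w = 1.0
        if op.j_residue == "P":
            w *= PRO_OPENING_WEIGHT
        if op.z_residue in "IL" and op.j_residue == "D":
            w *= ILD_OPENING_WEIGHT
        score += w
    return score


def rank_candidates(
    spectrum: Spectrum,
    candidates: list[CyclicPeptide],
    tol: float,
    *,
    min_n: int = 1,
) -> list[tuple[CyclicPeptide, MatchReport]]:
    """Rank candidates by fragment evidence.

    Sort key: matched b-ion count, then summed matched relative intensity,
    then longest contiguous series, then ring-opening propensity
    plausibility, all descending; deterministic final tie-break by
    canonical rotation (lexicographic).
    """
    scored = []
    for cand in candidates:
        rep = match_spectrum(spectrum, cand, tol, min_n=min_n)
        longest = max((s.length for s in rep.series), default=0)
        scored.append((cand, rep, longest))
    # The intensity key is rounded so that candidates matching the *same*
    # peak set (e.g. the reversed cycle, whose b-ion m/z multiset is
    # identical) tie exactly and fall through to the structural keys,
    # which do distinguish them: reversed matches scatter into short runs
    # and onto unfavored openings.
    scored.sort(
        key=lambda t: (
            -t[1].matched_b_count,
            -round(t[1].matched_intensity, 6),
            -t[2],
            -round(_propensity_score(t[1]), 6),
            canonical_rotation(t[0].encoded_seq),
        )
    )
    return [(c, r) for c, r, _ in scored]
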