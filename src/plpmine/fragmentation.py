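"""Theoretical MS/MS fragments of head-to-tail cyclic peptides.

Collision-induced dissociation of a homodetic cycle begins with a single
ring-opening event that linearizes the molecule into an acylium species;
b- and a-type ions then derive from that linear form. For a peptide of N
residues there are N possible openings, so the b-ion space is quadratic
in N, and every ion must carry a label that records *which* opening it
came from.

Labels follow the Ngoka-Gross convention ``x_nJZ``: ion type x (a or b),
residue count n, J the one-letter code of the residue that became the
N-terminus at the ring opening, Z the residue C-terminal at the cleavage
point (i.e. the residue preceding J in the cycle). When the ordered
adjacency (Z, J) occurs more than once around the cycle the bare label is
ambiguous; in that case J and Z each carry their 1-based position in the
encoded (as-translated) sequence, e.g. ``b3I3I2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .peptide_core import (
    CO_MASS,
    AMMONIA_MASS,
    PROTON_MASS,
    RESIDUE_MASSES,
    WATER_MASS,
    cyclic_monoisotopic_mass,
    mz_from_mass,
    validate_sequence,
)


@dataclass(frozen=True)
class RingOpening:
    """One of the N ways to linearize a cyclic peptide.

    ``opening_index`` (j) is the 1-based position, in the encoded sequence,
    of the residue that becomes the new N-terminus (J); ``z_index`` is the
    position of the cyclically preceding residue (Z), which becomes the
    C-terminus of the linearized form.
    """

    seq: str
    opening_index: int

    def __post_init__(self) -> None:
        validate_sequence(self.seq)
        if not 1 <= self.opening_index <= len(self.seq):
            raise ValueError(
                f"opening index {self.opening_index} out of range for "
                f"length-{len(self.seq)} sequence"
            )

    @property
    def z_index(self) -> int:
        j = self.opening_index
        return len(self.seq) if j == 1 else j - 1

    @property
    def j_residue(self) -> str:
        return self.seq[self.opening_index - 1]

    @property
    def z_residue(self) -> str:
        return self.seq[self.z_index - 1]

    @property
    def linearized(self) -> str:
        j = self.opening_index - 1
        return self.seq[j:] + self.seq[:j]


@dataclass(frozen=True)
class FragmentIon:
    label: str
    ion_type: str  # b | a | b-H2O | b-NH3 | a-H2O | a-NH3 | immonium | MH | M-H2O | M-CO
    n: int
    window: str
    mz: float
    charge: int = 1
    opening: RingOpening | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"non-positive m/z for {self.label}")


def linearize(seq: str, j: int) -> RingOpening:
    """Ring-open ``seq`` so that its 1-based position ``j`` becomes the N-terminus."""
    return RingOpening(seq, j)


def _adjacency_counts(seq: str) -> dict[tuple[str, str], int]:
    n = len(seq)
    counts: dict[tuple[str, str], int] = {}
    for k in range(n):
        pair = (seq[k], seq[(k + 1) % n])  # (Z, J) ordered around the cycle
        counts[pair] = counts.get(pair, 0) + 1
    return counts


def ion_label(ion_type: str, n: int, opening: RingOpening) -> str:
    """Ngoka-Gross label for an ion of ``n`` residues from ``opening``.

    The positional extension (e.g. ``b3I3I2``) is applied only when the
    ordered (Z, J) adjacency repeats in the cycle, in which case the bare
    JZ suffix would not identify the opening.
    """
    seq = opening.seq
    j, z = opening.j_residue, opening.z_residue
    ambiguous = _adjacency_counts(seq).get((z, j), 0) > 1
    prefix = ion_type.split("-")[0]  # b-H2O ions keep the b prefix in the stem
    suffix = ion_type[len(prefix):]  # "" or "-H2O"/"-NH3"
    if ambiguous:
        stem = f"{prefix}{n}{j}{opening.opening_index}{z}{opening.z_index}"
    else:
        stem = f"{prefix}{n}{j}{z}"
    return stem + suffix


def _b_mz(window: str) -> float:
    return sum(RESIDUE_MASSES[c] for c in window) + PROTON_MASS


def enumerate_fragments(
    seq: str,
    *,
    ion_types: Sequence[str] = ("b",),
    losses: bool = False,
    immonium: bool = False,
    min_n: int = 1,
    charge: int = 1,
) -> list[FragmentIon]:
    """Enumerate labeled theoretical fragments over all N ring openings.

    For each opening, b_n is generated for n = min_n..N-1; the full-length
    acylium b_N is identical for every opening (it is the cyclic [M+H]+)
    and is emitted once with the bare label ``bN``. a-ions are b - CO.
    Neutral losses (water, ammonia), when enabled, are applied at most once
    per ion. Immonium ions (residue - CO + proton) are emitted once per
    distinct residue and labeled with the one-letter code. Output is sorted
    by m/z with exact (label, m/z) duplicates removed.
    """
    validate_sequence(seq)
    n_res = len(seq)
    if n_res < 3:
        raise ValueError("ring fragmentation requires at least 3 residues")
    for t in ion_types:
        if t not in ("a", "b"):
            raise ValueError(f"unsupported ion type {t!r}")

    out: list[FragmentIon] = []

    def emit(label: str, ion_type: str, n: int, window: str, mz: float,
             opening: RingOpening | None) -> None:
        out.append(FragmentIon(label, ion_type, n, window, mz, charge, opening))

    for j in range(1, n_res + 1):
        op = RingOpening(seq, j)
        lin = op.linearized
        for n in range(max(1, min_n), n_res):
            window = lin[:n]
            b = _b_mz(window)
            if "b" in ion_types:
                emit(ion_label("b", n, op), "b", n, window, b, op)
                if losses:
                    emit(ion_label("b-H2O", n, op), "b-H2O", n, window, b - WATER_MASS, op)
                    emit(ion_label("b-NH3", n, op), "b-NH3", n, window, b - AMMONIA_MASS, op)
            if "a" in ion_types:
                a = b - CO_MASS
                emit(ion_label("a", n, op), "a", n, window, a, op)
                if losses:
                    emit(ion_label("a-H2O", n, op), "a-H2O", n, window, a - WATER_MASS, op)
                    emit(ion_label("a-NH3", n, op), "a-NH3", n, window, a - AMMONIA_MASS, op)

    # Full-ring acylium: one entry, opening unidentifiable.
    if "b" in ion_types:
        emit(f"b{n_res}", "b", n_res, seq, _b_mz(seq), None)

    if immonium:
        for res in sorted(set(seq)):
            mz = RESIDUE_MASSES[res] - CO_MASS + PROTON_MASS
            emit(res, "immonium", 1, res, mz, None)

    seen: set[tuple[str, float]] = set()
    unique: list[FragmentIon] = []
    for ion in out:
        key = (ion.label, round(ion.mz, 6))
        if key not in seen:
            seen.add(key)
            unique.append(ion)
    unique.sort(key=lambda f: (f.mz, f.label))
    return unique


def annotate_precursor_ions(seq: str, charge: int = 1) -> list[FragmentIon]:
    """[M+H]+, M-H2O and M-CO entries for the cyclic precursor."""
    m = cyclic_monoisotopic_mass(seq)
    mh = mz_from_mass(m, charge)
    label_charge = "" if charge == 1 else f" ({charge}+)"
    return [
        FragmentIon(f"[M+H]+{label_charge}", "MH", len(seq), seq, mh, charge),
        FragmentIon(f"M-H2O{label_charge}", "M-H2O", len(seq), seq, mh - WATER_MASS / charge, charge),
        FragmentIon(f"M-CO{label_charge}", "M-CO", len(seq), seq, mh - CO_MASS / charge, charge),
    ]


def theoretical_b_ion_set(seq: str, *, min_n: int = 1) -> list[FragmentIon]:
    """Plain b-ions over all openings plus [M+H]+ — the matcher's default space.

    The full-ring acylium bN is isobaric with the cyclic [M+H]+ and is
    represented by the precursor entry alone, so a single observed peak is
    never contested by two theoretical entries at the same m/z.
    """
    ions = [f for f in enumerate_fragments(seq, ion_types=("b",), min_n=min_n)
            if f.n < len(seq)]
    ions.extend(annotate_precursor_ions(seq)[:1])
    ions.sort(key=lambda f: (f.mz, f.label))
    return ions
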