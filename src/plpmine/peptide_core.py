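"""Exact-mass arithmetic for linear and head-to-tail cyclic peptides.

An orbitide is a homodetic macrocycle of 5-12 standard residues: its
monoisotopic mass is simply the sum of the residue (amino-acid-minus-water)
masses, because the head-to-tail amide bond consumes the terminal water of
the corresponding linear peptide.

Residue masses and the small-molecule constants come from pyteomics'
monoisotopic tables; nothing here is typed in by hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

from pyteomics import mass as _pmass

#: Monoisotopic residue masses (Da) for the 20 standard one-letter codes.
RESIDUE_MASSES: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

PROTON_MASS: float = _pmass.nist_mass["H+"][0][0]
WATER_MASS: float = _pmass.calculate_mass(formula="H2O")
AMMONIA_MASS: float = _pmass.calculate_mass(formula="NH3")
CO_MASS: float = _pmass.calculate_mass(formula="CO")

VALID_RESIDUES = frozenset(RESIDUE_MASSES)


class InvalidResidueError(ValueError):
    """A sequence contains a character that is not a standard residue code."""


def validate_sequence(seq: str) -> str:
    """Check that ``seq`` is a non-empty string of standard residue codes.

    Nonstandard or modified residues (lowercase, B/J/O/U/X/Z, etc.) are
    rejected outright rather than skipped, naming the offending character
    and its 1-based position.
    """
    if not isinstance(seq, str) or not seq:
        raise InvalidResidueError("sequence must be a non-empty residue string")
    for i, c in enumerate(seq):
        if c not in VALID_RESIDUES:
            raise InvalidResidueError(
                f"invalid residue code {c!r} at position {i + 1} in {seq!r}"
            )
    return seq


def cyclic_monoisotopic_mass(seq: str) -> float:
    """Monoisotopic mass (Da) of the head-to-tail cyclized peptide ``seq``.

    Equals the sum of residue masses: cyclization removes the terminal
    water of the linear chain.
    """
    validate_sequence(seq)
    return sum(RESIDUE_MASSES[c] for c in seq)


def linear_monoisotopic_mass(seq: str) -> float:
    """Monoisotopic mass (Da) of the linear peptide ``seq`` (free termini)."""
    return cyclic_monoisotopic_mass(seq) + WATER_MASS


def mz_from_mass(mass: float, charge: int = 1) -> float:
    """m/z of ``mass`` carrying ``charge`` protons."""
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    if not isinstance(charge, int) or charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge!r}")
    return (mass + charge * PROTON_MASS) / charge


def canonical_rotation(seq: str) -> str:
    """Lexicographically smallest rotation of ``seq``.

    Two encoded sequences denote the same macrocycle iff their canonical
    rotations are equal. Directionality is preserved: a reversed sequence
    is a different molecule and is NOT identified.
    """
    validate_sequence(seq)
    return min(seq[i:] + seq[:i] for i in range(len(seq)))


def round_mass(mass: float, ndigits: int = 3) -> float:
    """Round half-up to ``ndigits`` decimals, matching printed mass tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(mass)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CyclicPeptide:
    """An encoded linear sequence representing a head-to-tail macrocycle.

    ``encoded_seq`` is in the as-translated linear order, proto-N-terminus
    first (for a PLP: the residue after the conserved Asn first, the
    conserved proto-C-terminal Asp last).
    """

    encoded_seq: str
    name: str = ""
    gene: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        validate_sequence(self.encoded_seq)
        if not 1 <= len(self.encoded_seq) <= 50:
            raise ValueError(
                f"peptide length {len(self.encoded_seq)} outside 1-50 residues"
            )

    @property
    def cyclic_mass(self) -> float:
        return cyclic_monoisotopic_mass(self.encoded_seq)

    @property
    def canonical(self) -> str:
        return canonical_rotation(self.encoded_seq)

    def mh(self, charge: int = 1) -> float:
        """[M+zH]^z+ m/z of the cyclic peptide."""
        return mz_from_mass(self.cyclic_mass, charge)

    def __len__(self) -> int:
        return len(self.encoded_seq)
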