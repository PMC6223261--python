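"""Catalog-level statistics and conservation displays for PLP sets.

Works on any catalog TSV with columns name, encoded_seq, mass_mono, gene,
species; a transcription of the published 46-peptide PLP catalog ships
with the package. Statistics are computed over UNIQUE peptides (exact
encoded sequence), since the same peptide can occur in several taxa, and
logos are built per exact length with no alignment and no gaps: aligning
5-12 residue peptides inserts more gap than signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .peptide_core import (
    RESIDUE_MASSES,
    CyclicPeptide,
    cyclic_monoisotopic_mass,
)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

_INFRASPECIFIC_MARKERS = {"var", "var.", "ssp", "ssp.", "subsp", "subsp."}


def normalize_species(name: str) -> str:
    """Collapse infraspecific taxa (var./ssp.) onto the binomial."""
    tokens = name.split()
    out = []
    for tok in tokens:
        if tok.lower() in _INFRASPECIFIC_MARKERS:
            break
        out.append(tok)
    return " ".join(out[:2])


@dataclass
class Catalog:
    entries: list[CyclicPeptide]

    @property
    def unique_peptides(self) -> list[CyclicPeptide]:
        seen: dict[str, CyclicPeptide] = {}
        for e in self.entries:
            seen.setdefault(e.encoded_seq, e)
        return list(seen.values())

    @property
    def unique_sequences(self) -> list[str]:
        return [p.encoded_seq for p in self.unique_peptides]

    @property
    def species(self) -> set[str]:
        return {normalize_species(e.species) for e in self.entries if e.species}

    def __len__(self) -> int:
        return len(self.entries)


def packaged_catalog_path() -> Path:
    return Path(resources.files("plpmine").joinpath("data/plp_catalog.tsv"))


def load_catalog(path: str | Path | None = None, mass_tol: float = 0.001) -> Catalog:
    """Load a catalog TSV, verifying each printed mass against the sequence.

    A row whose sequence-derived cyclic mass disagrees with the mass_mono
    column by more than ``mass_tol`` Da is an error (it would mean either
    a transcription slip or a modified residue, which are out of scope).
    """
    if path is None:
        path = packaged_catalog_path()
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "encoded_seq": str})
    required = {"name", "encoded_seq", "mass_mono", "gene", "species"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"catalog missing columns: {sorted(missing)}")
    entries = []
    for idx, row in df.iterrows():
        seq = row["encoded_seq"]
        calc = cyclic_monoisotopic_mass(seq)
        if abs(calc - float(row["mass_mono"])) > mass_tol:
            raise ValueError(
                f"row {idx} ({row['name']}): sequence {seq} gives "
                f"{calc:.4f} Da but catalog lists {row['mass_mono']}"
            )
        entries.append(
            CyclicPeptide(
                encoded_seq=seq,
                name=row["name"],
                gene=row["gene"],
                species=row["species"],
            )
        )
    return Catalog(entries)


def length_histogram(catalog: Catalog) -> dict[int, int]:
    """Length -> count over unique peptides."""
    if not catalog.entries:
        raise ValueError("empty catalog")
    counts: dict[int, int] = {}
    for seq in catalog.unique_sequences:
        counts[len(seq)] = counts.get(len(seq), 0) + 1
    return dict(sorted(counts.items()))


@dataclass
class PositionFrequencyMatrix:
    """Per-position residue counts over n peptides of one exact length."""

    counts: pd.DataFrame  # index: position labels; columns: AA_ORDER
    n: int

    def __post_init__(self) -> None:
        sums = self.counts.sum(axis=1)
        if not (sums == self.n).all():
            raise ValueError("column sums must equal n (gapless, no alignment)")

    @property
    def length(self) -> int:
        return len(self.counts)

    def frequencies(self) -> pd.DataFrame:
        return self.counts / self.n


def positional_frequencies(catalog: Catalog, length: int) -> PositionFrequencyMatrix:
    """Gapless per-position counts over the unique peptides of ``length``."""
    seqs = [s for s in catalog.unique_sequences if len(s) == length]
    if not seqs:
        raise ValueError(f"no peptides of length {length}")
    counts = pd.DataFrame(
        0, index=[f"pos{i + 1}" for i in range(length)], columns=list(AA_ORDER)
    )
    for s in seqs:
        for i, c in enumerate(s):
            counts.loc[f"pos{i + 1}", c] += 1
    return PositionFrequencyMatrix(counts=counts, n=len(seqs))


def small_sample_correction(n: int, n_symbols: int = 20) -> float:
    """e_n = (s-1) / (2 n ln 2): the small-sample entropy bias in bits."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return (n_symbols - 1) / (2.0 * n * math.log(2.0))


def information_content(matrix: PositionFrequencyMatrix) -> np.ndarray:
    """Per-position information R_i = log2(20) - (H_i + e_n), clipped at 0.

    H_i is the Shannon entropy (bits) of the observed residue frequencies
    at position i; e_n corrects for the upward information bias of small
    samples. This is the quantity a sequence logo displays as stack height.
    """
    freqs = matrix.frequencies().to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    e_n = small_sample_correction(matrix.n)
    return np.clip(np.log2(20.0) - (entropy + e_n), 0.0, None)


FLANK_POSITIONS = ["P1", "P1'", "P2'", "P3'", "P4'"]


def flanking_matrix(precursors) -> PositionFrequencyMatrix:
    """Counts over the AEP-relevant flanks: the Asn (P1) and P1'-P4' tail.

    Build separate matrices for Asp-terminated and asp_lacking candidate
    sets to compare detected-style vs degenerate architectures.
    """
    precursors = list(precursors)
    if not precursors:
        raise ValueError("no precursor candidates supplied")
    counts = pd.DataFrame(0, index=FLANK_POSITIONS, columns=list(AA_ORDER))
    for c in precursors:
        aa = c.source.aa_seq
        p1 = aa[c.asn_position]
        row = [p1, *c.tail]
        for pos, res in zip(FLANK_POSITIONS, row):
            if res in AA_ORDER:
                counts.loc[pos, res] += 1
    return PositionFrequencyMatrix(counts=counts, n=len(precursors))


def composition_fractions(catalog: Catalog) -> pd.Series:
    """Residue -> fraction over the concatenated unique peptide sequences."""
    concat = "".join(catalog.unique_sequences)
    if not concat:
        raise ValueError("empty catalog")
    total = len(concat)
    return pd.Series(
        {aa: concat.count(aa) / total for aa in AA_ORDER}, name="fraction"
    )


#: Published census of known orbitides by plant family (count, size range).
ORBITIDE_FAMILY_CENSUS = pd.DataFrame(
    [
        ("Asteraceae", 46, "AEP", "5-12"),
        ("Caryophyllaceae", 104, "PCY1", "5-11"),
        ("Annonaceae", 28, "unknown", "6-9"),
        ("Rutaceae", 17, "unknown", "6-8"),
        ("Euphorbiaceae", 20, "unknown", "7-12"),
        ("Lamiaceae", 10, "unknown", "6-12"),
        ("Linaceae", 17, "unknown", "8-10"),
        ("Solanaceae", 4, "unknown", "8"),
        ("Santalaceae", 1, "unknown", "5"),
    ],
    columns=["family", "known_orbitides", "cyclization_enzyme", "size_range"],
)


def summary(catalog: Catalog) -> dict:
    """Headline numbers of a catalog: unique peptides, species, length modes."""
    hist = length_histogram(catalog)
    uniq = catalog.unique_sequences
    return {
        "n_entries": len(catalog.entries),
        "n_unique": len(uniq),
        "n_species": len(catalog.species),
        "length_histogram": hist,
        "min_length": min(hist),
        "max_length": max(hist),
        "all_end_in_asp": all(s.endswith("D") for s in uniq),
    }


def plot_logo(matrix: PositionFrequencyMatrix, ax=None):
    """Crude information-content logo: stacked letter heights in bits.

    The numeric matrix is the tested artifact; this plot is a convenience.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(0.8 * matrix.length + 1, 3))
    info = information_content(matrix)
    freqs = matrix.frequencies()
    for i, pos in enumerate(freqs.index):
        bottom = 0.0
        col = freqs.loc[pos]
        for aa in col.sort_values().index:
            h = col[aa] * info[i]
            if h <= 0:
                continue
            ax.text(i + 1, bottom + h / 2, aa, ha="center", va="center",
                    fontsize=8 + 10 * col[aa], family="monospace")
            bottom += h
    ax.set_xlim(0.5, matrix.length + 0.5)
    ax.set_ylim(0, math.log2(20))
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    return ax
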