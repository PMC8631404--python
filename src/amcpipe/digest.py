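"""In-silico proteolytic digestion and molecular weight.

Label-based and label-free MS intensities (LFQ/TMT/SILAC) scale with the
number of peptides an instrument can observe for a protein, so converting
intensities into copy numbers requires a per-protein detectability
correction: the count of theoretical enzymatic peptides in the detectable
length window (6-29 residues).  iBAQ values are already peptide-count
normalized and take a factor of 1.

Cleavage is C-terminal to the enzyme's target residues (trypsin: K/R,
lysC: K) with zero missed cleavages and no proline exception.  Molecular
weights are average (not monoisotopic) masses: the concentration formulas
need bulk mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "DigestSpec",
    "ProteinSequence",
    "digest_fragments",
    "count_theoretical_peptides",
    "molecular_weight",
    "detectability_factor",
    "read_fasta",
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
]

# Expasy average residue masses (free amino acid minus one water), g/mol.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153
# UniProt wildcard X: mean of the 20 standard residues.  B/J/O/U/Z rejected.
_MEAN_RESIDUE_MASS = sum(AVERAGE_RESIDUE_MASS.values()) / len(AVERAGE_RESIDUE_MASS)
_VALID_RESIDUES = frozenset(AVERAGE_RESIDUE_MASS) | {"X"}


@dataclass(frozen=True)
class DigestSpec:
    """Enzyme and detectable-length window for theoretical digestion."""

    enzyme: str = "trypsin"
    cleavage_residues: frozenset[str] = frozenset({"K", "R"})
    min_len: int = 6
    max_len: int = 29

    def __post_init__(self) -> None:
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError("require 1 <= min_len <= max_len")

    @classmethod
    def trypsin(cls, min_len: int = 6, max_len: int = 29) -> "DigestSpec":
        return cls("trypsin", frozenset({"K", "R"}), min_len, max_len)

    @classmethod
    def lysc(cls, min_len: int = 6, max_len: int = 29) -> "DigestSpec":
        return cls("lysC", frozenset({"K"}), min_len, max_len)


@dataclass
class ProteinSequence:
    """A protein sequence with optional pre-supplied molecular weight."""

    identifier: str
    residues: str
    mol_weight: float | None = None  # g/mol

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for {self.identifier}")
        self.residues = self.residues.upper()
        validate_residues(self.residues, self.identifier)


def validate_residues(residues: str, identifier: str = "?") -> None:
    for pos, aa in enumerate(residues, start=1):
        if aa not in _VALID_RESIDUES:
            raise ValueError(
                f"invalid residue {aa!r} at position {pos} in sequence {identifier}"
            )


def digest_fragments(residues: str, spec: DigestSpec) -> list[str]:
    """Cut immediately after every cleavage residue (no missed cleavages).

    Returns all fragments unfiltered; their lengths sum to the sequence
    length by construction.
    """
    fragments: list[str] = []
    start = 0
    for i, aa in enumerate(residues):
        if aa in spec.cleavage_residues:
            fragments.append(residues[start : i + 1])
            start = i + 1
    if start < len(residues):
        fragments.append(residues[start:])
    return fragments


def count_theoretical_peptides(seq: ProteinSequence, spec: DigestSpec) -> int:
    """Number of digest fragments with length in [min_len, max_len]."""
    frags = digest_fragments(seq.residues, spec)
    return sum(1 for f in frags if spec.min_len <= len(f) <= spec.max_len)


def molecular_weight(seq: ProteinSequence) -> float:
    """Average mass in g/mol: residue masses plus one water.

    A ``mol_weight`` already present on the sequence (e.g. taken from the
    source data) is returned unchanged without recomputation.
    """
    if seq.mol_weight is not None:
        return seq.mol_weight
    return sum(
        AVERAGE_RESIDUE_MASS.get(aa, _MEAN_RESIDUE_MASS) for aa in seq.residues
    ) + WATER_MASS


def detectability_factor(
    seq: ProteinSequence, data_type: str, spec: DigestSpec | None = None
) -> float | None:
    """Detectability scaling for one protein under one quantification type.

    LFQ/TMT/SILAC: theoretical peptide count.  iBAQ: 1 (already normalized
    by definition).  A zero peptide count for a non-iBAQ entry returns
    ``None`` with a logged warning — the entry must be excluded upstream
    (division guard).
    """
    dt = data_type.strip().upper()
    if dt == "IBAQ":
        return 1.0
    if dt not in {"LFQ", "TMT", "SILAC"}:
        raise ValueError(f"unknown data type {data_type!r}")
    count = count_theoretical_peptides(seq, spec or DigestSpec.trypsin())
    if count == 0:
        logger.warning(
            "excluding %s: zero theoretical peptides for %s data", seq.identifier, dt
        )
        return None
    return float(count)


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a protein FASTA; recognizes the UniProt ``sp|ACC|NAME`` dialect.

    The identifier is the first whitespace-delimited header token; for
    UniProt-style headers the accession field is used.
    """
    sequences: list[ProteinSequence] = []
    for record in SeqIO.parse(str(path), "fasta"):
        ident = record.id.split()[0]
        parts = ident.split("|")
        if len(parts) == 3 and parts[0] in {"sp", "tr"}:
            ident = parts[1]
        sequences.append(ProteinSequence(identifier=ident, residues=str(record.seq)))
    return sequences
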