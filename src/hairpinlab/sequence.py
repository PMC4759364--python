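"""Sequence-level analysis of two-strand antiparallel beta-hairpin peptides.

A hairpin of length ``L`` folds so that residue ``i`` of the N-side strand
faces residue ``L - i`` of the C-side strand.  For the 19-mer laminin-derived
peptides this positional register puts the backbone hydrogen bonds on the
even-index pairs (2,17), (4,15), (6,13), (8,11) — two bonds per pair, one in
each donor/acceptor direction, labelled HB1..HB8 counting from the termini —
and leaves the odd-index pairs available for side-chain (hydrophobic or
ionic) contacts.  The census of these non-covalent pairs is the sequence-only
stability predictor this module computes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

__all__ = [
    "Polarity",
    "Residue",
    "PeptideSequence",
    "FacingPair",
    "HBondDef",
    "Census",
    "EF1_SEQUENCE",
    "EF2_SEQUENCE",
    "THREE_LETTER",
    "parse_sequence",
    "classify_residue",
    "facing_pairs",
    "hbond_register",
    "hydrophobic_pairs",
    "ionic_pairs",
    "noncovalent_census",
    "census_table",
]

# Laminin alpha1/alpha2 LG4-module loop peptides (capped Ace-...-Nme).
EF1_SEQUENCE = "DYATLQLQEGRLHFMFDLG"
EF2_SEQUENCE = "DFATVQLRNGFPYFSYDLG"


class Polarity(str, Enum):
    """Four-group residue classification used by the pair census."""

    POSITIVE = "positive-polar"
    NEGATIVE = "negative-polar"
    UNCHARGED = "uncharged-polar"
    NONPOLAR = "non-polar"


# Side-chain polarity groups.  TYR and CYS count as uncharged polar, PRO and
# GLY as non-polar; HIS is grouped with the positively charged residues.
_POLARITY_TABLE: dict[str, Polarity] = {
    **{c: Polarity.POSITIVE for c in "RKH"},
    **{c: Polarity.NEGATIVE for c in "DE"},
    **{c: Polarity.UNCHARGED for c in "STNQYCW"},
    **{c: Polarity.NONPOLAR for c in "AVLIMFPG"},
}

THREE_LETTER: dict[str, str] = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


class InvalidSequenceError(ValueError):
    """Raised when a sequence string contains a non-standard letter."""


class NoRegisterError(ValueError):
    """Raised when a peptide is too short to define a hairpin register."""


@dataclass(frozen=True)
class Residue:
    """One amino acid with its 1-based position in the uncapped chain."""

    index: int
    code: str
    polarity: Polarity

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"residue index must be >= 1, got {self.index}")
        if self.code not in _POLARITY_TABLE:
            raise InvalidSequenceError(f"unknown residue code {self.code!r}")

    @property
    def name(self) -> str:
        """Three-letter residue name (e.g. ``TYR``)."""
        return THREE_LETTER[self.code]


@dataclass(frozen=True)
class PeptideSequence:
    """Capped peptide: residues numbered 1..L, caps carry no index."""

    residues: tuple[Residue, ...]
    n_term_cap: str | None = None
    c_term_cap: str | None = None
    label: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, index: int) -> Residue:
        """Residue by 1-based position."""
        if not 1 <= index <= len(self.residues):
            raise IndexError(f"residue index {index} out of range 1..{len(self)}")
        return self.residues[index - 1]

    @property
    def one_letter(self) -> str:
        return "".join(r.code for r in self.residues)


@dataclass(frozen=True)
class FacingPair:
    """A stabilizing residue pair: positional register (i + j = L, j - i >= 2)
    for hbond-register/hydrophobic/none kinds, or a nearby charged pair for
    the ionic kind."""

    i: int
    j: int
    kind: str  # hbond-register | hydrophobic | ionic | none

    def __post_init__(self) -> None:
        if self.j <= self.i:
            raise ValueError(f"facing pair ({self.i},{self.j}) must have i < j")
        if self.kind != "ionic" and self.j - self.i < 2:
            raise ValueError(f"facing pair ({self.i},{self.j}) too close")


@dataclass(frozen=True)
class HBondDef:
    """One register hydrogen bond: donor N-H (or C=O) to acceptor partner.

    ``donor_atom``/``acceptor_atom`` name the backbone groups: the amide
    donor is the ``H`` on ``N``, the carbonyl acceptor is the ``O`` on ``C``.
    """

    label: str
    donor_residue: int
    donor_atom: str
    acceptor_residue: int
    acceptor_atom: str

    def describe(self, seq: PeptideSequence) -> str:
        d, a = seq[self.donor_residue], seq[self.acceptor_residue]
        return (
            f"{self.label}: {d.name}{d.index}-NH ... OC-{a.name}{a.index}"
            if self.donor_atom == "H"
            else f"{self.label}: {d.name}{d.index}-CO ... HN-{a.name}{a.index}"
        )


@dataclass(frozen=True)
class Census:
    """Counts of stabilizing facing pairs for one peptide."""

    label: str
    n_hbond_registers: int
    n_hydrophobic: int
    n_ionic: int
    pairs: tuple[FacingPair, ...] = field(default=(), compare=False)

    @property
    def total(self) -> int:
        return self.n_hbond_registers + self.n_hydrophobic + self.n_ionic


def classify_residue(code: str) -> Polarity:
    """Map a one-letter amino-acid code to its polarity group.

    R/K/H are positive polar, D/E negative polar, S/T/N/Q/Y/C/W uncharged
    polar, and A/V/L/I/M/F/P/G non-polar (hydrophobic).
    """
    try:
        return _POLARITY_TABLE[code]
    except KeyError:
        raise InvalidSequenceError(f"unknown residue code {code!r}") from None


def parse_sequence(one_letter: str, label: str = "", capped: bool = True) -> PeptideSequence:
    """Build a :class:`PeptideSequence` from a one-letter string.

    Parameters
    ----------
    one_letter:
        Standard one-letter codes, N- to C-terminus.
    label:
        Free-text name carried through analyses (e.g. ``"EF1"``).
    capped:
        If true, record acetyl (Ace) and N-methyl amide (Nme) terminal caps.
        Caps never receive a residue index; numbering is 1..L over the
        amino acids only.
    """
    if not one_letter:
        raise InvalidSequenceError("empty sequence")
    residues = []
    for pos, code in enumerate(one_letter, start=1):
        if code not in _POLARITY_TABLE:
            raise InvalidSequenceError(
                f"invalid residue {code!r} at position {pos} of {label or one_letter!r}"
            )
        residues.append(Residue(pos, code, _POLARITY_TABLE[code]))
    return PeptideSequence(
        residues=tuple(residues),
        n_term_cap="Ace" if capped else None,
        c_term_cap="Nme" if capped else None,
        label=label,
    )


def facing_pairs(seq: PeptideSequence) -> list[FacingPair]:
    """All cross-strand pairs (i, L-i) of the positional hairpin register.

    Pairs are emitted for 1 <= i < L-i with (L-i) - i >= 2, ordered by i.
    For L = 19 this gives the eight pairs (1,18)..(8,11); the two-residue
    turn (9,10) and the terminal residue 19 stay unpaired.
    """
    L = len(seq)
    if L < 5:
        raise NoRegisterError(f"need at least 5 residues for a register, got {L}")
    pairs = []
    for i in range(1, L):
        j = L - i
        if j - i < 2:
            break
        pairs.append(FacingPair(i, j, _pair_kind(seq, i, j)))
    return pairs


def _pair_kind(seq: PeptideSequence, i: int, j: int) -> str:
    if i % 2 == 0:
        return "hbond-register"
    if seq[i].polarity is Polarity.NONPOLAR and seq[j].polarity is Polarity.NONPOLAR:
        return "hydrophobic"
    return "none"


def hbond_register(seq: PeptideSequence) -> list[HBondDef]:
    """The HB1..HB8 backbone hydrogen bonds of the hairpin register.

    Each even-index facing pair (i, j) carries two inter-strand backbone
    bonds: i(N-H) -> j(C=O) and i(C=O) <- j(N-H).  Labels count pairwise
    from the termini inward: HB1/HB2 on (2,17) ... HB7/HB8 on (8,11).
    """
    bonds: list[HBondDef] = []
    n = 0
    for pair in facing_pairs(seq):
        if pair.kind != "hbond-register":
            continue
        i, j = pair.i, pair.j
        bonds.append(HBondDef(f"HB{2 * n + 1}", i, "H", j, "O"))
        bonds.append(HBondDef(f"HB{2 * n + 2}", j, "H", i, "O"))
        n += 1
    return bonds


def hydrophobic_pairs(seq: PeptideSequence) -> list[FacingPair]:
    """Facing pairs (odd register positions) where both residues are non-polar."""
    return [p for p in facing_pairs(seq) if p.kind == "hydrophobic"]


# Central-turn window and sequence-separation cutoff for the ionic rule.
IONIC_REGION = (8, 12)
IONIC_MAX_SEPARATION = 2


def ionic_pairs(seq: PeptideSequence) -> list[FacingPair]:
    """Oppositely charged residue pairs near the turn.

    Heuristic: a salt bridge is plausible between a positive-polar and a
    negative-polar residue at most :data:`IONIC_MAX_SEPARATION` positions
    apart, both inside the central window :data:`IONIC_REGION` (the turn
    region, where the chain bends back on itself).
    """
    lo, hi = IONIC_REGION
    charged = [
        r for r in seq.residues
        if lo <= r.index <= hi and r.polarity in (Polarity.POSITIVE, Polarity.NEGATIVE)
    ]
    pairs = []
    for a_idx, a in enumerate(charged):
        for b in charged[a_idx + 1:]:
            if a.polarity is not b.polarity and b.index - a.index <= IONIC_MAX_SEPARATION:
                pairs.append(FacingPair(a.index, b.index, "ionic"))
    return pairs


def noncovalent_census(seq: PeptideSequence) -> Census:
    """Count the stabilizing non-covalent pairs of a 19-residue hairpin.

    Totals the hydrogen-bonded register pairs (always 4 for L = 19), the
    hydrophobic facing pairs, and any central ionic pairs.
    """
    register = [p for p in facing_pairs(seq) if p.kind == "hbond-register"]
    phob = hydrophobic_pairs(seq)
    ionic = ionic_pairs(seq)
    return Census(
        label=seq.label,
        n_hbond_registers=len(register),
        n_hydrophobic=len(phob),
        n_ionic=len(ionic),
        pairs=tuple(register + phob + ionic),
    )


def census_table(seqs: Iterable[PeptideSequence]) -> "pandas.DataFrame":  # noqa: F821
    """Tabulate the stabilizing pairs of one or more peptides.

    Columns: label, pair_i, pair_j, kind, residue_i, residue_j.
    """
    import pandas as pd

    rows = []
    for seq in seqs:
        census = noncovalent_census(seq)
        for p in census.pairs:
            rows.append({
                "label": census.label,
                "pair_i": p.i,
                "pair_j": p.j,
                "kind": p.kind,
                "residue_i": seq[p.i].name,
                "residue_j": seq[p.j].name,
            })
    return pd.DataFrame(
        rows, columns=["label", "pair_i", "pair_j", "kind", "residue_i", "residue_j"]
    )
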