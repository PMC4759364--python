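"""DSSP-style secondary-structure assignment and the beta-sheet rate.

Backbone hydrogen bonds are detected with the Kabsch-Sander electrostatic
energy (partial charges on the C=O and N-H dipoles); the bond pattern is
then reduced to per-residue codes: E (extended strand in a ladder),
B (isolated beta bridge), H (alpha helix), G (3-10 helix), T (turn),
C (coil).  The per-frame fraction of E residues is the beta-sheet formation
rate used as the scalar order parameter for autocorrelation analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .structure import Frame, Trajectory

logger = logging.getLogger("hairpinlab")

__all__ = [
    "SSAssignment",
    "SheetRateSeries",
    "ks_hbond_energy",
    "KS_ENERGY_CUTOFF",
    "amide_hydrogen_position",
    "backbone_hbond_set",
    "assign_secondary_structure",
    "beta_sheet_rate",
    "sheet_rate_series",
]

# Kabsch-Sander constants: q1*q2*f = 0.084 e * 332 kcal*A/(mol*e^2);
# a bond is declared below -0.5 kcal/mol.
KS_COUPLING = 0.084 * 332.0  # kcal/mol * Angstrom
KS_ENERGY_CUTOFF = -0.5      # kcal/mol
ANGSTROM_PER_NM = 10.0
NH_BOND_NM = 0.101


def ks_hbond_energy(
    donor_n: np.ndarray,
    donor_h: np.ndarray,
    acceptor_c: np.ndarray,
    acceptor_o: np.ndarray,
) -> float:
    """Kabsch-Sander electrostatic H-bond energy, kcal/mol (positions in nm).

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN), r in Angstrom.
    """
    def dist(a: np.ndarray, b: np.ndarray) -> float:
        return float(np.linalg.norm(a - b)) * ANGSTROM_PER_NM

    r_on = dist(acceptor_o, donor_n)
    r_ch = dist(acceptor_c, donor_h)
    r_oh = dist(acceptor_o, donor_h)
    r_cn = dist(acceptor_c, donor_n)
    if min(r_on, r_ch, r_oh, r_cn) <= 0.0:
        raise ValueError("coincident atoms in H-bond energy evaluation")
    return KS_COUPLING * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)


def amide_hydrogen_position(
    n_pos: np.ndarray, ca_pos: np.ndarray, prev_c_pos: np.ndarray
) -> np.ndarray:
    """Reconstruct the amide hydrogen from N, CA and the preceding C.

    The N-H vector (1.01 Angstrom) points opposite the bisector of the two
    in-plane N bonds, the standard sp2 amide geometry.
    """
    u1 = n_pos - prev_c_pos
    u2 = n_pos - ca_pos
    u1 = u1 / np.linalg.norm(u1)
    u2 = u2 / np.linalg.norm(u2)
    bis = u1 + u2
    return n_pos + NH_BOND_NM * bis / np.linalg.norm(bis)


def _residue_atoms(frame: Frame) -> dict[int, dict[str, np.ndarray]]:
    """Backbone atom positions keyed by residue index (caps excluded)."""
    residues: dict[int, dict[str, np.ndarray]] = {}
    names: dict[int, str] = {}
    for atom in frame.atoms:
        if atom.residue_index < 1 or atom.residue_name in ("ACE", "NME"):
            continue
        residues.setdefault(atom.residue_index, {})[atom.atom_name] = atom.position
        names[atom.residue_index] = atom.residue_name
    for idx, atoms in residues.items():
        atoms["_resname"] = names[idx]  # type: ignore[assignment]
    return residues


def backbone_hbond_set(frame: Frame, min_separation: int = 2) -> set[tuple[int, int]]:
    """All (donor, acceptor) residue pairs with a Kabsch-Sander bond.

    Proline has no amide hydrogen and never donates; a missing hydrogen is
    reconstructed from N, CA and the preceding carbonyl carbon.  The first
    residue (no preceding C and no stored H) cannot donate.  Pairs closer
    than ``min_separation`` in sequence are excluded.
    """
    residues = _residue_atoms(frame)
    indices = sorted(residues)
    bonds: set[tuple[int, int]] = set()
    for d in indices:
        datoms = residues[d]
        if datoms.get("_resname") == "PRO":
            continue
        if "N" not in datoms:
            continue
        h = datoms.get("H")
        if h is None:
            prev = residues.get(d - 1, {})
            if "C" not in prev or "CA" not in datoms:
                continue
            h = amide_hydrogen_position(datoms["N"], datoms["CA"], prev["C"])
        for a in indices:
            if abs(a - d) < min_separation:
                continue
            aatoms = residues[a]
            if "C" not in aatoms or "O" not in aatoms:
                continue
            e = ks_hbond_energy(datoms["N"], h, aatoms["C"], aatoms["O"])
            if e < KS_ENERGY_CUTOFF:
                bonds.add((d, a))
    return bonds


@dataclass(frozen=True)
class SSAssignment:
    """Per-residue secondary-structure codes for one frame."""

    residue_indices: tuple[int, ...]
    codes: str
    frame_time: float | None = None

    def count(self, *symbols: str) -> int:
        return sum(self.codes.count(s) for s in symbols)


def assign_secondary_structure(frame: Frame) -> SSAssignment:
    """Assign E/B/H/G/T/C codes to every residue of one frame.

    Bridge rules (antiparallel and parallel) follow the Kabsch-Sander
    H-bond patterns; two or more consecutive bridged residues form an E
    ladder, an isolated bridge is B.  Runs of i -> i+4 bonds give H,
    i -> i+3 give G, leftover turn residues T.  Priority H > E > B > G > T.
    """
    residues = _residue_atoms(frame)
    if not residues:
        raise ValueError("frame has no residues to assign")
    indices = sorted(residues)
    for idx in indices:
        missing = {"N", "CA", "C", "O"} - set(residues[idx])
        if missing:
            raise ValueError(f"residue {idx} lacks backbone atoms {sorted(missing)}")

    don = backbone_hbond_set(frame)

    def hb(d: int, a: int) -> bool:
        return (d, a) in don

    pos = {idx: k for k, idx in enumerate(indices)}
    n = len(indices)
    bridged = np.zeros(n, dtype=bool)
    for i in indices:
        for j in indices:
            if j - i < 3:
                continue
            anti = (hb(i, j) and hb(j, i)) or (hb(j + 1, i - 1) and hb(i + 1, j - 1))
            para = (hb(j, i - 1) and hb(i + 1, j)) or (hb(i, j - 1) and hb(j + 1, i))
            if anti or para:
                bridged[pos[i]] = bridged[pos[j]] = True

    turn3 = {i for i in indices if hb(i + 3, i)}
    turn4 = {i for i in indices if hb(i + 4, i)}
    turn5 = {i for i in indices if hb(i + 5, i)}

    codes = ["C"] * n
    # Turns first (lowest priority, overwritten below).
    for starts, span in ((turn3, 3), (turn4, 4), (turn5, 5)):
        for i in starts:
            for r in range(i + 1, i + span):
                if r in pos:
                    codes[pos[r]] = "T"
    # 3-10 helix: two consecutive 3-turn starts.
    for i in indices:
        if i in turn3 and (i + 1) in turn3:
            for r in range(i + 1, i + 4):
                if r in pos:
                    codes[pos[r]] = "G"
    # Beta: ladders (E) over isolated bridges (B).
    for k in range(n):
        if bridged[k]:
            ladder = (k > 0 and bridged[k - 1]) or (k + 1 < n and bridged[k + 1])
            codes[k] = "E" if ladder else "B"
    # Alpha helix: two consecutive 4-turn starts, highest priority.
    for i in indices:
        if i in turn4 and (i + 1) in turn4:
            for r in range(i + 1, i + 5):
                if r in pos:
                    codes[pos[r]] = "H"
    return SSAssignment(residue_indices=tuple(indices), codes="".join(codes),
                        frame_time=frame.time)


def beta_sheet_rate(assignment: SSAssignment, include_bridges: bool = False) -> float:
    """Fraction of residues assigned to beta sheet (E, optionally also B)."""
    symbols = ("E", "B") if include_bridges else ("E",)
    return assignment.count(*symbols) / len(assignment.codes)


@dataclass(frozen=True)
class SheetRateSeries:
    """Per-frame beta-sheet formation rate."""

    values: np.ndarray
    frame_interval: float  # ps

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def std(self) -> float:
        return float(np.std(self.values))


def sheet_rate_series(traj: Trajectory, include_bridges: bool = False) -> SheetRateSeries:
    """Beta-sheet rate for every frame of a trajectory."""
    values = np.array([
        beta_sheet_rate(assign_secondary_structure(f), include_bridges)
        for f in traj.frames
    ])
    return SheetRateSeries(values=values, frame_interval=traj.frame_interval)
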