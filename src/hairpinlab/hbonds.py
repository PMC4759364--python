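"""Geometric tracking of the register hydrogen bonds across a trajectory.

The hairpin's eight backbone bonds (HB1..HB8, defined from the sequence
register) are followed frame by frame: their H...O length, whether each is
formed under a distance+angle criterion, and the per-frame count of formed
bonds.  The reported "length" is the hydrogen-to-oxygen distance — the
formed-bond scale (~0.20 nm) — not the heavier N...O separation (~0.29 nm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .secstruct import amide_hydrogen_position
from .sequence import HBondDef
from .structure import Frame, Trajectory

__all__ = [
    "HBondCriteria",
    "HBondTrace",
    "hbond_length",
    "hbond_formed",
    "hbond_traces",
    "hbond_count_series",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Formation criterion: donor-acceptor distance and H-donor-acceptor angle.

    Defaults (0.35 nm, 30 deg) are the common MD-analysis convention.
    """

    max_da_distance: float = 0.35  # nm, N...O
    max_hda_angle: float = 30.0    # degrees

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0 or self.max_hda_angle <= 0:
            raise ValueError("criteria must be positive")


def _donor_acceptor_positions(
    frame: Frame, bond: HBondDef
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(donor N, donor H, acceptor O) positions for one register bond, nm."""
    n_idx = frame.find(bond.donor_residue, "N")
    o_idx = frame.find(bond.acceptor_residue, "O")
    if n_idx < 0 or o_idx < 0:
        raise ValueError(f"{bond.label}: missing N or O atom in frame")
    n_pos = frame.atoms[n_idx].position
    h_idx = frame.find(bond.donor_residue, "H")
    if h_idx >= 0:
        h_pos = frame.atoms[h_idx].position
    else:
        ca_idx = frame.find(bond.donor_residue, "CA")
        c_prev = frame.find(bond.donor_residue - 1, "C")
        if ca_idx < 0 or c_prev < 0:
            raise ValueError(f"{bond.label}: cannot reconstruct amide H for "
                             f"residue {bond.donor_residue}")
        h_pos = amide_hydrogen_position(
            n_pos, frame.atoms[ca_idx].position, frame.atoms[c_prev].position
        )
    return n_pos, h_pos, frame.atoms[o_idx].position


def hbond_length(frame: Frame, bond: HBondDef) -> float:
    """H...O distance of one register bond in one frame, nm."""
    _, h_pos, o_pos = _donor_acceptor_positions(frame, bond)
    return float(np.linalg.norm(h_pos - o_pos))


def hbond_formed(
    frame: Frame, bond: HBondDef, criteria: HBondCriteria = HBondCriteria()
) -> bool:
    """Whether the bond satisfies the distance+angle formation criterion.

    Formed iff the donor-acceptor (N...O) distance is within
    ``max_da_distance`` and the H-N...O angle within ``max_hda_angle``.
    """
    n_pos, h_pos, o_pos = _donor_acceptor_positions(frame, bond)
    da = o_pos - n_pos
    d_da = np.linalg.norm(da)
    if d_da > criteria.max_da_distance:
        return False
    dh = h_pos - n_pos
    cosang = np.dot(dh, da) / (np.linalg.norm(dh) * d_da)
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return bool(angle <= criteria.max_hda_angle)


@dataclass(frozen=True)
class HBondTrace:
    """Per-frame record of one labelled bond."""

    label: str
    lengths: np.ndarray        # nm, H...O
    formed: np.ndarray         # bool

    @property
    def mean_length(self) -> float:
        return float(np.mean(self.lengths))

    @property
    def std_length(self) -> float:
        return float(np.std(self.lengths))


def hbond_traces(
    traj: Trajectory,
    bonds: list[HBondDef],
    criteria: HBondCriteria = HBondCriteria(),
) -> list[HBondTrace]:
    """Track every supplied bond across the trajectory."""
    traces = []
    for bond in bonds:
        lengths = np.array([hbond_length(f, bond) for f in traj.frames])
        formed = np.array([hbond_formed(f, bond, criteria) for f in traj.frames])
        traces.append(HBondTrace(label=bond.label, lengths=lengths, formed=formed))
    return traces


def hbond_count_series(
    traj: Trajectory,
    bonds: list[HBondDef],
    criteria: HBondCriteria = HBondCriteria(),
) -> tuple[np.ndarray, float, float]:
    """Per-frame number of formed register bonds, plus mean and std."""
    traces = hbond_traces(traj, bonds, criteria)
    counts = np.sum([t.formed for t in traces], axis=0)
    return counts, float(counts.mean()), float(counts.std())
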