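"""Trajectory container and multi-model PDB input/output.

Internal coordinates are in nanometres throughout the package (PDB files are
in Angstrom and converted on the way in/out).  Frames carry a reduced atom
set — backbone N, H, CA, C, O plus one CB pseudo-atom per non-glycine
residue — which is all the downstream descriptors need.  Terminal caps, when
present, sit at residue index 0 (acetyl) and L+1 (N-methyl amide) and are
excluded from every analysis selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("hairpinlab")

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "SUPPORTED_ATOMS",
    "read_pdb_models",
    "write_pdb_models",
    "select_atoms",
    "EmptyStructureError",
    "FrameMismatchError",
    "EmptySelectionError",
]

SUPPORTED_ATOMS = ("N", "H", "CA", "C", "O", "CB")

NM_PER_ANGSTROM = 0.1


class EmptyStructureError(ValueError):
    """PDB file or frame contains no usable atom records."""


class FrameMismatchError(ValueError):
    """Models of a multi-model file carry inconsistent atom sets."""


class EmptySelectionError(ValueError):
    """An atom selection matched nothing."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: residue index (1-based; caps 0 / L+1), names, position in nm."""

    residue_index: int
    residue_name: str
    atom_name: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"bad position for atom {self.atom_name}: {self.position}")
        object.__setattr__(self, "position", pos)


@dataclass
class Frame:
    """One conformation: an ordered list of atoms and an optional time stamp."""

    atoms: list[AtomRecord]
    time: float | None = None  # ps

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, nm."""
        return np.array([a.position for a in self.atoms])

    def with_coords(self, coords: np.ndarray) -> "Frame":
        """Copy of this frame with replaced coordinates (same atom metadata)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coordinate shape {coords.shape} != ({len(self.atoms)}, 3)")
        return Frame(
            atoms=[replace(a, position=c.copy()) for a, c in zip(self.atoms, coords)],
            time=self.time,
        )

    def atom_key(self) -> list[tuple[int, str]]:
        return [(a.residue_index, a.atom_name) for a in self.atoms]

    def find(self, residue_index: int, atom_name: str) -> int:
        """Index of the named atom, or -1 if absent."""
        for k, a in enumerate(self.atoms):
            if a.residue_index == residue_index and a.atom_name == atom_name:
                return k
        return -1


@dataclass
class Trajectory:
    """Ordered frames with a constant atom layout."""

    frames: list[Frame]
    frame_interval: float = 1.0  # ps
    label: str = ""
    temperature: float | None = None  # K

    def __post_init__(self) -> None:
        if not self.frames:
            raise EmptyStructureError("trajectory needs at least one frame")
        key = self.frames[0].atom_key()
        for m, fr in enumerate(self.frames[1:], start=2):
            if fr.atom_key() != key:
                raise FrameMismatchError(f"frame {m} atom set differs from frame 1")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.frames[0])

    @property
    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) array, nm."""
        return np.array([f.coords for f in self.frames])

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps (from stored stamps, else the frame interval)."""
        return np.array([
            f.time if f.time is not None else k * self.frame_interval
            for k, f in enumerate(self.frames)
        ])


def read_pdb_models(path: str | Path) -> Trajectory:
    """Read a (multi-model) PDB file into a :class:`Trajectory`.

    Coordinates are converted Angstrom -> nm.  Atoms outside the supported
    backbone+CB set are skipped (one summary log line).  Residue numbering is
    taken from the file.  Models must share an identical atom layout.
    """
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    pdb_file = pdb.PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure(model=None)  # AtomArrayStack
    except Exception as exc:  # no ATOM records or malformed
        raise EmptyStructureError(f"{path}: no readable coordinates ({exc})") from exc
    if stack.array_length() == 0:
        raise EmptyStructureError(f"{path}: no ATOM records")

    keep = np.isin(stack.atom_name, SUPPORTED_ATOMS)
    n_skipped = int((~keep).sum())
    if n_skipped:
        logger.info("%s: skipped %d unsupported atoms", path.name, n_skipped)
    stack = stack[..., keep]
    if stack.array_length() == 0:
        raise EmptyStructureError(f"{path}: no supported atoms after filtering")

    frames = []
    for m in range(stack.stack_depth()):
        model = stack[m]
        atoms = [
            AtomRecord(
                residue_index=int(model.res_id[k]),
                residue_name=str(model.res_name[k]),
                atom_name=str(model.atom_name[k]),
                position=model.coord[k] * NM_PER_ANGSTROM,
            )
            for k in range(model.array_length())
        ]
        frames.append(Frame(atoms=atoms))
    return Trajectory(frames=frames, label=path.stem)


def write_pdb_models(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB v3.3 file (nm -> Angstrom)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    if traj.n_atoms == 0:
        raise EmptyStructureError("cannot write a trajectory with no atoms")
    n_atoms = traj.n_atoms
    template = traj.frames[0]
    arrays = []
    for fr in traj.frames:
        arr = struc.AtomArray(n_atoms)
        arr.coord = fr.coords / NM_PER_ANGSTROM
        arr.res_id = np.array([a.residue_index for a in template.atoms])
        arr.res_name = np.array([a.residue_name for a in template.atoms])
        arr.atom_name = np.array([a.atom_name for a in template.atoms])
        arr.element = np.array([a.atom_name[0] for a in template.atoms])
        arr.chain_id = np.full(n_atoms, "A")
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def select_atoms(
    frame_or_traj: Frame | Trajectory,
    selection: str | Sequence[str] = "main-chain",
    residue_range: tuple[int, int] | None = None,
) -> list[int]:
    """Resolve a named atom selection to a stable, duplicate-free index list.

    ``main-chain`` selects {N, CA, O} — the chiral carbon, amide nitrogen and
    carbonyl oxygen.  The carbonyl carbon is deliberately not part of it; pass
    a custom list such as ``("N", "CA", "C", "O")`` to include it.  Other
    names: ``CA``, ``heavy`` (N, CA, C, O, CB) and ``all``.  Cap records
    (residue index 0 or L+1, i.e. outside 1..L) are always excluded.

    ``residue_range`` restricts to an inclusive 1-based residue interval.
    """
    frame = frame_or_traj.frames[0] if isinstance(frame_or_traj, Trajectory) else frame_or_traj
    named = {
        "main-chain": ("N", "CA", "O"),
        "CA": ("CA",),
        "heavy": ("N", "CA", "C", "O", "CB"),
        "all": SUPPORTED_ATOMS,
    }
    if isinstance(selection, str):
        if selection not in named:
            raise ValueError(
                f"unknown selection {selection!r}; use one of {sorted(named)} or an atom-name list"
            )
        wanted = named[selection]
    else:
        wanted = tuple(selection)

    indices = []
    for k, atom in enumerate(frame.atoms):
        if atom.residue_index < 1 or atom.residue_name in ("ACE", "NME"):
            continue  # terminal caps carry no analysis weight
        if atom.atom_name not in wanted:
            continue
        if residue_range is not None and not (
            residue_range[0] <= atom.residue_index <= residue_range[1]
        ):
            continue
        indices.append(k)
    if not indices:
        raise EmptySelectionError(f"selection {selection!r} matched no atoms")
    return indices


def series_to_csv(times: Iterable[float], values: Iterable[float], path: str | Path,
                  value_name: str = "value") -> None:
    """Export a time series as a two-column CSV (time_ps, <value_name>)."""
    import pandas as pd

    pd.DataFrame({"time_ps": list(times), value_name: list(values)}).to_csv(
        path, index=False
    )
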