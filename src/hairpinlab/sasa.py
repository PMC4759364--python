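"""Solvent-accessible surface area by the Shrake-Rupley point-counting method.

Each atom is expanded by the probe radius and covered with a deterministic
Fibonacci lattice of test points; points falling inside any neighbouring
expanded sphere are buried, and the exposed fraction times the expanded
sphere area gives that atom's contribution.  The lattice is fixed (no RNG)
so repeated runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import Frame, Trajectory

__all__ = [
    "SasaResult",
    "shrake_rupley",
    "sasa_series",
    "fibonacci_sphere",
    "atom_radius",
    "ATOM_RADII_NM",
    "CB_RADIUS_CLASS_NM",
    "MissingRadiusError",
]


class MissingRadiusError(KeyError):
    """An atom name has no entry in the radius table."""


# Bondi-type van der Waals radii for backbone atoms (nm).
ATOM_RADII_NM = {"N": 0.155, "C": 0.170, "CA": 0.170, "O": 0.152, "H": 0.110}

# The CB pseudo-atom stands for the whole side chain; three size classes.
CB_RADIUS_CLASS_NM = {"small": 0.20, "medium": 0.25, "large": 0.30}
_CB_CLASS_BY_RESIDUE = {
    **{r: "small" for r in ("ALA", "SER", "CYS")},
    **{r: "medium" for r in ("THR", "VAL", "PRO", "ASN", "ASP", "LEU", "ILE",
                             "MET", "GLU", "GLN", "LYS")},
    **{r: "large" for r in ("PHE", "TYR", "TRP", "ARG", "HIS")},
}

DEFAULT_PROBE_NM = 0.14
DEFAULT_N_POINTS = 960


def atom_radius(atom_name: str, residue_name: str = "") -> float:
    """Radius (nm) of a supported atom; CB radius depends on the residue."""
    if atom_name == "CB":
        cls = _CB_CLASS_BY_RESIDUE.get(residue_name, "medium")
        return CB_RADIUS_CLASS_NM[cls]
    try:
        return ATOM_RADII_NM[atom_name]
    except KeyError:
        raise MissingRadiusError(f"no radius for atom {atom_name!r}") from None


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice, shape (n_points, 3)."""
    k = np.arange(n_points)
    golden = (1 + np.sqrt(5)) / 2
    z = 1 - (2 * k + 1) / n_points
    phi = 2 * np.pi * k / golden
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass(frozen=True)
class SasaResult:
    per_atom: np.ndarray   # nm^2
    probe_radius: float    # nm
    n_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def shrake_rupley(
    frame: Frame,
    probe_radius: float = DEFAULT_PROBE_NM,
    n_points: int = DEFAULT_N_POINTS,
) -> SasaResult:
    """Numerical SASA of one frame.

    Per atom: (exposed lattice points / n_points) x 4 pi (r_i + probe)^2.
    """
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    coords = frame.coords
    radii = np.array([atom_radius(a.atom_name, a.residue_name) for a in frame.atoms])
    expanded = radii + probe_radius
    lattice = fibonacci_sphere(n_points)

    n = len(frame.atoms)
    per_atom = np.empty(n)
    # Neighbour cutoff: spheres i and j can only intersect within R_i + R_j.
    for i in range(n):
        points = coords[i] + expanded[i] * lattice
        d_centers = np.linalg.norm(coords - coords[i], axis=1)
        neighbors = np.where((d_centers < expanded + expanded[i]) & (np.arange(n) != i))[0]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((points - coords[j]) ** 2, axis=1)
            exposed &= d2 > expanded[j] ** 2
        per_atom[i] = exposed.mean() * 4 * np.pi * expanded[i] ** 2
    return SasaResult(per_atom=per_atom, probe_radius=probe_radius, n_points=n_points)


def sasa_series(
    traj: Trajectory,
    probe_radius: float = DEFAULT_PROBE_NM,
    n_points: int = DEFAULT_N_POINTS,
) -> tuple[np.ndarray, float, float]:
    """Per-frame total SASA plus its mean and standard deviation (nm^2)."""
    totals = np.array([
        shrake_rupley(f, probe_radius, n_points).total for f in traj.frames
    ])
    return totals, float(totals.mean()), float(totals.std())
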