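"""Optimal superposition and structural descriptors: RMSD, R_g, RMSF.

RMSD is computed after a least-squares rigid-body fit (Kabsch superposition,
reflection-corrected), R_g about the mass-weighted centre of mass, and RMSF
about the iterated time-average structure.  All lengths in nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import Frame, Trajectory, select_atoms

__all__ = [
    "SuperpositionResult",
    "DescriptorSeries",
    "kabsch_superpose",
    "rmsd_series",
    "radius_of_gyration",
    "rg_series",
    "rmsf",
    "ATOM_MASSES",
]

# Atomic masses (u) for the supported backbone + CB atom names.  The CB
# pseudo-atom of the coarse-grained frames stands for the whole side chain
# but is given a plain carbon mass; R_g weighting is dominated by geometry.
ATOM_MASSES = {"N": 14.007, "H": 1.008, "CA": 12.011, "C": 12.011, "O": 15.999,
               "CB": 12.011}


@dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares rigid fit: x_fit = (x - mobile_mean) @ rotation.T + target_mean."""

    rotation: np.ndarray      # (3,3), det +1
    translation: np.ndarray   # (3,), nm
    rmsd: float               # nm

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class DescriptorSeries:
    """Per-frame scalar descriptor (RMSD or Rg), nm."""

    values: np.ndarray
    frame_interval: float  # ps
    descriptor: str

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def std(self) -> float:
        return float(np.std(self.values))


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Weighted least-squares rigid-body superposition of two point sets.

    Returns the proper rotation (no reflection) and translation minimizing
    the weighted RMSD of ``mobile`` onto ``reference``, plus that minimum.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(f"point sets must both be (n,3); got {mobile.shape} vs {reference.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a unique superposition")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative with positive sum")

    mob_mean = np.average(mobile, axis=0, weights=w)
    ref_mean = np.average(reference, axis=0, weights=w)
    mob_c = mobile - mob_mean
    ref_c = reference - ref_mean
    # Guard against degenerate (collinear) configurations.
    if np.linalg.matrix_rank(mob_c * w[:, None], tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) point configuration")

    rot, rssd = Rotation.align_vectors(ref_c, mob_c, weights=w)
    matrix = rot.as_matrix()
    rmsd = float(rssd / np.sqrt(w.sum()))
    translation = ref_mean - mob_mean @ matrix.T
    return SuperpositionResult(rotation=matrix, translation=translation, rmsd=rmsd)


def _coords_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(
    traj: Trajectory,
    reference: Frame,
    fit_selection: str | list[int] = "main-chain",
    calc_selection: str | list[int] | None = None,
) -> DescriptorSeries:
    """Per-frame RMSD to a reference after rigid-body fitting.

    Each frame is superposed on the reference over ``fit_selection`` and the
    RMSD evaluated over ``calc_selection`` (defaults to the fit selection).
    Selections may be named sets or explicit atom-index lists; named
    selections are resolved on both trajectory and reference, which must
    agree in size.
    """
    fit_t = select_atoms(traj, fit_selection) if isinstance(fit_selection, str) else list(fit_selection)
    fit_r = select_atoms(reference, fit_selection) if isinstance(fit_selection, str) else list(fit_selection)
    if calc_selection is None:
        calc_t, calc_r = fit_t, fit_r
    elif isinstance(calc_selection, str):
        calc_t = select_atoms(traj, calc_selection)
        calc_r = select_atoms(reference, calc_selection)
    else:
        calc_t = calc_r = list(calc_selection)
    if len(fit_t) != len(fit_r) or len(calc_t) != len(calc_r):
        raise ValueError("selection size differs between trajectory and reference")

    ref_coords = reference.coords
    values = np.empty(len(traj))
    for k, frame in enumerate(traj.frames):
        coords = frame.coords
        sup = kabsch_superpose(coords[fit_t], ref_coords[fit_r])
        values[k] = _coords_rmsd(sup.apply(coords[calc_t]), ref_coords[calc_r])
    return DescriptorSeries(values=values, frame_interval=traj.frame_interval,
                            descriptor="RMSD")


def radius_of_gyration(
    frame: Frame,
    selection: str | list[int] = "heavy",
    mass_weighted: bool = True,
) -> float:
    """Radius of gyration sqrt(sum w_i |r_i - r_com|^2 / sum w_i), nm."""
    idx = select_atoms(frame, selection) if isinstance(selection, str) else list(selection)
    if not idx:
        raise ValueError("empty selection")
    coords = frame.coords[idx]
    if mass_weighted:
        w = np.array([ATOM_MASSES[frame.atoms[i].atom_name] for i in idx])
    else:
        w = np.ones(len(idx))
    com = np.average(coords, axis=0, weights=w)
    return float(np.sqrt(np.average(np.sum((coords - com) ** 2, axis=1), weights=w)))


def rg_series(
    traj: Trajectory,
    selection: str | list[int] = "heavy",
    mass_weighted: bool = True,
) -> DescriptorSeries:
    """Per-frame radius of gyration."""
    idx = select_atoms(traj, selection) if isinstance(selection, str) else list(selection)
    values = np.array([
        radius_of_gyration(f, idx, mass_weighted=mass_weighted) for f in traj.frames
    ])
    return DescriptorSeries(values=values, frame_interval=traj.frame_interval,
                            descriptor="Rg")


def rmsf(
    traj: Trajectory,
    fit_selection: str | list[int] = "main-chain",
    target_atoms: str | list[int] = "CA",
    n_mean_iterations: int = 2,
) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the mean structure, nm.

    The reference is the iterated time-average: frames are fitted to the
    first frame, averaged, then refitted to that average (repeated
    ``n_mean_iterations`` times) before fluctuations are measured.  Fitting
    on a sub-selection (e.g. the N-side strand, residues 1-10) exposes the
    relative motion of the unfitted strand.
    """
    if len(traj) < 2:
        raise ValueError("RMSF needs at least 2 frames")
    fit_idx = select_atoms(traj, fit_selection) if isinstance(fit_selection, str) else list(fit_selection)
    tgt_idx = select_atoms(traj, target_atoms) if isinstance(target_atoms, str) else list(target_atoms)

    all_coords = traj.coords  # (F, A, 3)
    reference = all_coords[0]
    fitted = all_coords
    for _ in range(n_mean_iterations):
        fitted = np.empty_like(all_coords)
        for k in range(all_coords.shape[0]):
            sup = kabsch_superpose(all_coords[k][fit_idx], reference[fit_idx])
            fitted[k] = sup.apply(all_coords[k])
        reference = fitted.mean(axis=0)
    fluct = fitted[:, tgt_idx, :] - reference[tgt_idx]
    return np.sqrt(np.mean(np.sum(fluct ** 2, axis=2), axis=0))
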