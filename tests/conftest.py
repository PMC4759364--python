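"""Shared fixtures: peptide sequences, ideal-geometry frames, tiny ensembles."""

import numpy as np
import pytest

from hairpinlab.sequence import EF1_SEQUENCE, EF2_SEQUENCE, parse_sequence
from hairpinlab.structure import AtomRecord, Frame, Trajectory
from hairpinlab.synthetic import (
    EnergyModel,
    build_hairpin,
    extended_torsions,
    helix_torsions,
    ideal_hairpin_torsions,
    mc_sweep,
)


@pytest.fixture(scope="session")
def ef1():
    return parse_sequence(EF1_SEQUENCE, label="EF1", capped=True)


@pytest.fixture(scope="session")
def ef2():
    return parse_sequence(EF2_SEQUENCE, label="EF2", capped=True)


@pytest.fixture(scope="session")
def ideal_frame(ef1):
    """Ideal antiparallel hairpin conformation of EF1."""
    return build_hairpin(ef1, ideal_hairpin_torsions(19))


@pytest.fixture(scope="session")
def helix_frame(ef1):
    return build_hairpin(ef1, helix_torsions(19))


@pytest.fixture(scope="session")
def extended_frame(ef1):
    return build_hairpin(ef1, extended_torsions(19))


@pytest.fixture(scope="session")
def wobble_trajectory(ef1):
    """Short Monte Carlo trajectory near the folded state (8 frames)."""
    model = EnergyModel(ef1)
    rng = np.random.default_rng(42)
    state = ideal_hairpin_torsions(19)
    frames = [build_hairpin(ef1, state, time=0.0)]
    energy = model.energy_of_state(state)
    for k in range(7):
        state, energy, _ = mc_sweep(state, 300.0, model, rng, energy=energy)
        frames.append(build_hairpin(ef1, state, time=float(k + 1)))
    return Trajectory(frames=frames, frame_interval=1.0, label="wobble")


def toy_frame(positions, atom_name="CA"):
    """Frame of bare atoms at the given positions (one residue each)."""
    atoms = [
        AtomRecord(residue_index=i + 1, residue_name="ALA",
                   atom_name=atom_name, position=np.asarray(p, dtype=float))
        for i, p in enumerate(positions)
    ]
    return Frame(atoms=atoms)
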