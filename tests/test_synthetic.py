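"""Hairpin builder, census-derived energy, Metropolis and replica exchange."""

import math

import numpy as np
import pytest

from hairpinlab.hbonds import hbond_length
from hairpinlab.secstruct import assign_secondary_structure
from hairpinlab.sequence import hbond_register, parse_sequence
from hairpinlab.synthetic import (
    EnergyModel,
    ReplicaLadder,
    PUBLISHED_LADDER_K,
    TorsionState,
    ToyEnergyParams,
    build_hairpin,
    demultiplexed_trajectories,
    extended_torsions,
    generate_ensembles,
    helix_torsions,
    ideal_hairpin_torsions,
    mc_sweep,
    reduced_temperature,
    remd_ladder,
    remd_run,
    swap_probability,
    toy_energy,
)


class TestBuilder:
    def test_ideal_hairpin_closes_register_bonds(self, ef1, ideal_frame):
        for bond in hbond_register(ef1):
            assert hbond_length(ideal_frame, bond) < 0.25

    def test_extended_chain_opens_register(self, ef1, extended_frame):
        # every register bond is far beyond formation range; the outer
        # pairs (larger sequence separation) open beyond 1 nm
        for bond in hbond_register(ef1):
            sep = abs(bond.donor_residue - bond.acceptor_residue)
            assert hbond_length(extended_frame, bond) > (1.0 if sep > 5 else 0.5)

    def test_helix_assigns_h(self, helix_frame):
        assert "H" in assign_secondary_structure(helix_frame).codes

    def test_atom_inventory(self, ef2):
        frame = build_hairpin(ef2, ideal_hairpin_torsions(19))
        names = {}
        for a in frame.atoms:
            names.setdefault(a.residue_index, set()).add(a.atom_name)
        assert "H" not in names[12]          # proline
        assert "CB" not in names[10]         # glycine
        assert "H" not in names[1]           # no preceding carbonyl
        assert names[5] == {"N", "H", "CA", "C", "O", "CB"}

    def test_torsion_count_must_match(self, ef1):
        with pytest.raises(ValueError):
            build_hairpin(ef1, extended_torsions(10))

    def test_torsion_range_validated(self):
        with pytest.raises(ValueError):
            TorsionState(phi=(190.0,), psi=(0.0,))


class TestToyEnergy:
    def test_ideal_hairpin_engages_all_wells(self, ef1):
        params = ToyEnergyParams()
        state = ideal_hairpin_torsions(19)
        e = toy_energy(state, params, ef1)
        # 8 H-bond wells fully engaged; side-chain wells partially; bias ~ 0
        assert e < -(8 * params.w_hb) * 0.9

    def test_extended_chain_has_no_attraction(self, ef1):
        params = ToyEnergyParams(torsion_bias_strength=0.0)
        e = toy_energy(extended_torsions(19), params, ef1)
        assert e > -0.05

    def test_ef1_deeper_than_ef2_at_equal_weights(self, ef1, ef2):
        params = ToyEnergyParams()
        state = ideal_hairpin_torsions(19)
        assert toy_energy(state, params, ef1) < toy_energy(state, params, ef2)

    def test_frame_and_state_paths_agree_on_wells(self, ef1, ideal_frame):
        params = ToyEnergyParams(torsion_bias_strength=0.0)
        e_state = toy_energy(ideal_hairpin_torsions(19), params, ef1)
        e_frame = toy_energy(ideal_frame, params, ef1)
        assert e_frame == pytest.approx(e_state, abs=1e-6)

    def test_negative_depths_rejected(self):
        with pytest.raises(ValueError):
            ToyEnergyParams(w_hb=-1.0)


class TestMcSweep:
    def test_zero_temperature_limit_never_increases_energy(self, ef1):
        model = EnergyModel(ef1)
        rng = np.random.default_rng(0)
        state = ideal_hairpin_torsions(19)
        e = model.energy_of_state(state)
        for _ in range(5):
            state, e_new, _ = mc_sweep(state, 1e-9, model, rng, energy=e)
            assert e_new <= e + 1e-12
            e = e_new

    def test_identical_seeds_identical_trajectories(self, ef1):
        model = EnergyModel(ef1)
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(123)
            state = ideal_hairpin_torsions(19)
            for _ in range(3):
                state, _, _ = mc_sweep(state, 320.0, model, rng)
            outs.append(state)
        assert outs[0] == outs[1]

    def test_double_well_occupancy_matches_boltzmann(self, ef1):
        """1-DOF double well: occupancy ratio equals the Boltzmann factor."""

        class DoubleWell:
            """Two minima at phi_0 = +/-90 deg with an energy offset."""

            n_residues = 1
            params = ToyEnergyParams()

            def __init__(self, offset):
                self.offset = offset

            def energy(self, phi, psi):
                x = phi[0] / 90.0
                base = 2.0 * (x * x - 1.0) ** 2
                return base + (self.offset if phi[0] > 0 else 0.0)

            def energy_of_state(self, state):
                return self.energy(np.array(state.phi), np.array(state.psi))

        # hot chain: the 2-unit barrier is ~1.4 T_red, so wells exchange often
        offset = 0.5
        t_k = 2000.0
        t_red = reduced_temperature(t_k)
        model = DoubleWell(offset)
        rng = np.random.default_rng(7)
        state = TorsionState(phi=(-90.0,), psi=(0.0,))
        n_right = 0
        n_total = 4000
        e = model.energy_of_state(state)
        for _ in range(n_total):
            state, e, _ = mc_sweep(state, t_k, model, rng, energy=e)
            n_right += state.phi[0] > 0
        expected = 1.0 / (1.0 + math.exp(offset / t_red))
        observed = n_right / n_total
        # 3 sigma with a conservative effective sample size (correlated chain)
        se = math.sqrt(expected * (1 - expected) / (n_total / 20))
        assert abs(observed - expected) < 3 * se


class TestLadder:
    def test_table_ladder_matches_published_protocol(self):
        ladder = remd_ladder(mode="published")
        assert ladder.n_replicas == 48
        assert ladder.temperatures[0] == 300.0
        assert ladder.temperatures[-1] == 450.5
        gaps = np.diff(ladder.temperatures)
        assert gaps.min() >= 2.5 and gaps.max() <= 4.0

    def test_geometric_mode_equal_ratios(self):
        ladder = remd_ladder(300.0, 450.5, n=4, mode="geometric")
        t = np.array(ladder.temperatures)
        ratios = t[1:] / t[:-1]
        np.testing.assert_allclose(ratios, ratios[0])
        assert t[0] == pytest.approx(300.0) and t[-1] == pytest.approx(450.5)

    def test_invalid_ladders_rejected(self):
        with pytest.raises(ValueError):
            remd_ladder(300.0, 450.5, n=1)
        with pytest.raises(ValueError):
            remd_ladder(400.0, 300.0, n=4)
        with pytest.raises(ValueError):
            ReplicaLadder((300.0, 300.0))


class TestReplicaExchange:
    def test_swap_probability_one_for_equal_energies(self):
        assert swap_probability(300.0, 350.0, -3.7, -3.7) == 1.0

    def test_swap_probability_detailed_balance_ratio(self):
        # p(swap)/p(reverse) must equal the product-Boltzmann ratio
        t1, t2, e1, e2 = 300.0, 360.0, -5.0, -3.0
        b1 = 1.0 / reduced_temperature(t1)
        b2 = 1.0 / reduced_temperature(t2)
        forward = swap_probability(t1, t2, e1, e2)
        backward = swap_probability(t1, t2, e2, e1)
        assert forward / backward == pytest.approx(math.exp((b1 - b2) * (e1 - e2)))

    def test_two_state_two_replica_stationary_distribution(self):
        """Exchange moves preserve the product-Boltzmann distribution.

        Two replicas at T1 < T2, each holding a two-state system with
        energies (0, de).  Flip moves (Metropolis) plus package swap moves
        must keep the exact product distribution stationary; empirical
        occupancies of the 4 joint states are compared at 3 sigma.
        """
        de = 0.4
        t1, t2 = 300.0, 400.0
        b1 = 1.0 / reduced_temperature(t1)
        b2 = 1.0 / reduced_temperature(t2)
        rng = np.random.default_rng(11)
        s1, s2 = 0, 0  # state of replica at t1, t2
        counts = np.zeros((2, 2))
        n_steps = 40_000
        for _ in range(n_steps):
            # flip attempts
            for which, beta in ((0, b1), (1, b2)):
                s = s1 if which == 0 else s2
                delta = de if s == 0 else -de
                if delta <= 0 or rng.random() < math.exp(-beta * delta):
                    if which == 0:
                        s1 = 1 - s1
                    else:
                        s2 = 1 - s2
            # exchange attempt through the package's acceptance rule
            p = swap_probability(t1, t2, de * s1, de * s2)
            if p >= 1.0 or rng.random() < p:
                s1, s2 = s2, s1
            counts[s1, s2] += 1
        z1 = 1 + math.exp(-b1 * de)
        z2 = 1 + math.exp(-b2 * de)
        for a in (0, 1):
            for b in (0, 1):
                expected = (math.exp(-b1 * de * a) / z1) * (math.exp(-b2 * de * b) / z2)
                observed = counts[a, b] / n_steps
                se = math.sqrt(expected * (1 - expected) / (n_steps / 10))
                assert abs(observed - expected) < 3 * se, (a, b)

    def test_flat_potential_visits_temperatures_uniformly(self, ef1):
        flat = ToyEnergyParams(w_hb=0.0, w_phob=0.0, w_ionic=0.0,
                               k_repulsion=0.0, torsion_bias_strength=0.0)
        model = EnergyModel(ef1, flat)
        ladder = remd_ladder(300.0, 400.0, n=4, mode="geometric")
        run = remd_run(model, ladder, sweeps=200, exchange_interval=1, seed=5)
        history = run.replica_temperature_history
        n_epochs = history.shape[0]
        for replica in range(4):
            occup = np.bincount(history[:, replica], minlength=4) / n_epochs
            se = math.sqrt(0.25 * 0.75 / (n_epochs / 4))
            assert np.all(np.abs(occup - 0.25) < 3 * se)

    def test_exchange_statistics_bookkeeping(self, ef1):
        model = EnergyModel(ef1)
        ladder = remd_ladder(300.0, 450.0, n=4, mode="geometric")
        run = remd_run(model, ladder, sweeps=60, exchange_interval=5, seed=2)
        assert np.all(run.exchange_accepts <= run.exchange_attempts)
        assert run.exchange_attempts.sum() > 0

    def test_mean_energy_increases_with_temperature(self, ef1):
        model = EnergyModel(ef1)
        ladder = ReplicaLadder((300.0, 360.0, 430.0))
        run = remd_run(model, ladder, sweeps=400, exchange_interval=5, seed=3)
        means = run.mean_energy_by_temperature()
        ordered = [means[t] for t in ladder.temperatures]
        assert ordered[0] < ordered[-1]

    def test_full_determinism_under_fixed_seed(self, ef1):
        model = EnergyModel(ef1)
        ladder = remd_ladder(300.0, 400.0, n=3, mode="geometric")
        a = remd_run(model, ladder, sweeps=40, exchange_interval=4, seed=9)
        b = remd_run(model, ladder, sweeps=40, exchange_interval=4, seed=9)
        assert a.samples == b.samples
        np.testing.assert_array_equal(
            a.replica_temperature_history, b.replica_temperature_history
        )


class TestEnsembles:
    def test_same_seed_identical_output(self):
        a = generate_ensembles("EF1", n_frames=20, seed=4,
                               analysis_temperatures=(300.0,))
        b = generate_ensembles("EF1", n_frames=20, seed=4,
                               analysis_temperatures=(300.0,))
        np.testing.assert_array_equal(a[300.0].coords, b[300.0].coords)

    def test_requested_frame_count_and_metadata(self):
        trajs = generate_ensembles("EF2", n_frames=25, seed=1,
                                   analysis_temperatures=(300.0, 343.0))
        assert set(trajs) == {300.0, 343.0}
        for t, traj in trajs.items():
            assert len(traj) == 25
            assert traj.temperature == t

    def test_unknown_profile_rejected(self):
        with pytest.raises(ValueError):
            generate_ensembles("EF9", n_frames=5)

    def test_demultiplex_skips_unsampled_temperatures(self, ef1):
        model = EnergyModel(ef1)
        ladder = remd_ladder(300.0, 400.0, n=3, mode="geometric")
        run = remd_run(model, ladder, sweeps=30, exchange_interval=5, seed=0,
                       sample_interval=5)
        trajs = demultiplexed_trajectories(run, ef1, temperatures=[300.0])
        assert list(trajs) == [300.0]
        # 19 x 6 atoms minus H of residue 1 and CB of the two glycines
        assert trajs[300.0].n_atoms == 19 * 6 - 3
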