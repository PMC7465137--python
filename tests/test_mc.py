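"""Metropolis sampler: acceptance rule, bookkeeping, schedules, scans."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from glutencg import (
    AnnealSchedule,
    BeadChainSystem,
    EnergyModelParams,
    MCConfig,
    ProteinSequence,
    build_system,
    metropolis_step,
    run_annealed,
    run_mc,
    salt_scan,
    total_energy,
)


def neutral_dimer(bead_radius=0.5, bond_k=30.0):
    params = EnergyModelParams(
        bead_radius=bead_radius, bond_force_constant=bond_k, salt_mM=80.0
    )
    return BeadChainSystem(
        coords=np.array([[750.0, 750.0, 750.0], [754.1, 750.0, 750.0]]),
        charges=np.zeros(2, dtype=int),
        ion_coords=np.empty((0, 3)),
        ion_charges=np.empty(0, dtype=int),
        restraints=[],
        params=params,
    )


def free_chain_system(n=40, b=4.1):
    """Neutral chain with a vanishing hard core: bonds only."""
    from glutencg.synthetic import generate_ideal_chain

    params = EnergyModelParams(bead_radius=1e-9, salt_mM=80.0)
    conf = generate_ideal_chain(n, b, seed=1)
    return BeadChainSystem(
        coords=conf.coordinates + 750.0,
        charges=np.zeros(n, dtype=int),
        ion_coords=np.empty((0, 3)),
        ion_charges=np.empty(0, dtype=int),
        restraints=[],
        params=params,
    )


class TestMetropolisStep:
    def test_zero_delta_proposals_always_accepted(self):
        # two free beads (no bonds evaluated? bonds exist) -> use bond_k = 0
        system = neutral_dimer(bond_k=0.0)
        rng = np.random.default_rng(0)
        config = MCConfig(single_bead_step=0.3)
        accepted = [
            metropolis_step(system, "single_bead", rng, config)[1] for _ in range(200)
        ]
        assert all(accepted)

    def test_overlap_proposals_always_rejected(self):
        # huge beads: almost any displacement overlaps the partner
        system = neutral_dimer(bead_radius=2.049, bond_k=0.0)
        rng = np.random.default_rng(1)
        config = MCConfig(single_bead_step=3.0)
        for _ in range(500):
            metropolis_step(system, "single_bead", rng, config)
            d = np.linalg.norm(system.coords[1] - system.coords[0])
            assert d >= 2 * system.params.bead_radius


class TestRunMC:
    def test_frame_count_follows_thinning(self):
        system = free_chain_system(n=10)
        ens = run_mc(
            system,
            MCConfig(n_equilibration_sweeps=5, n_production_sweeps=57, thinning=10),
        )
        assert ens.n_frames == 5  # floor(57 / 10)

    def test_zero_production_errors(self):
        system = free_chain_system(n=5)
        with pytest.raises(ValueError):
            run_mc(system, MCConfig(n_production_sweeps=0))

    def test_same_seed_reproduces_ensemble(self):
        def go():
            system = free_chain_system(n=12)
            return run_mc(
                system,
                MCConfig(
                    n_equilibration_sweeps=20, n_production_sweeps=50,
                    thinning=5, seed=123,
                ),
            )

        a, b = go(), go()
        assert np.array_equal(a.frames, b.frames)
        assert np.array_equal(a.energies, b.energies)

    def test_free_chain_recovers_freely_jointed_ree(self):
        """Without interactions the chain is ideal: <Ree^2> = (n-1)<b^2>."""
        n = 40
        system = free_chain_system(n=n)
        ens = run_mc(
            system,
            MCConfig(
                n_equilibration_sweeps=200, n_production_sweeps=2000,
                thinning=10, seed=42,
            ),
        )
        ree2 = ens.ree**2
        # harmonic bonds fluctuate: <b^2> = b0^2 + 1/k
        b2 = 4.1**2 + 1.0 / system.params.bond_force_constant
        expected = (n - 1) * b2
        se = ree2.std(ddof=1) / math.sqrt(len(ree2))
        assert abs(ree2.mean() - expected) < 3 * max(se, 0.05 * expected / 3)

    def test_acceptance_rates_neither_zero_nor_stuck(self, unrestrained_run):
        for move, (acc, att) in unrestrained_run.acceptance.items():
            assert 0 < acc <= att, move
        # local moves on a dense hard-sphere chain must see some rejections
        for move in ("single_bead", "pivot", "crankshaft"):
            acc, att = unrestrained_run.acceptance[move]
            assert acc < att, move

    def test_energy_drift_below_tolerance(self, unrestrained_run):
        assert unrestrained_run.metadata["energy_drift_kT"] < 1e-6

    def test_saved_frames_keep_hard_sphere_invariant(self, restrained_run):
        sigma = 2 * 2.0
        for frame in restrained_run.frames[::5]:
            d = np.linalg.norm(frame[:, None] - frame[None, :], axis=2)
            iu = np.triu_indices(len(frame), 1)
            assert d[iu].min() >= sigma - 1e-9


class TestBoltzmannDimer:
    def test_bond_length_distribution_matches_closed_form(self):
        """Detailed-balance check: sampled P(b) vs r^2 exp(-k(b-b0)^2/2)."""
        system = neutral_dimer(bead_radius=0.5, bond_k=30.0)
        rng = np.random.default_rng(7)
        config = MCConfig(single_bead_step=0.35)
        samples = []
        for sweep in range(100000):
            for _ in range(2):
                metropolis_step(system, "single_bead", rng, config)
            if sweep >= 2000 and sweep % 10 == 0:
                samples.append(
                    float(np.linalg.norm(system.coords[1] - system.coords[0]))
                )
        samples = np.asarray(samples)
        k, b0, sigma = 30.0, 4.1, 1.0
        lo, hi = max(sigma, b0 - 4 / math.sqrt(k)), b0 + 4 / math.sqrt(k)
        edges = np.linspace(lo, hi, 16)
        observed, _ = np.histogram(samples[(samples >= lo) & (samples <= hi)], edges)
        # bin probabilities by fine-grained quadrature of r^2 exp(-beta u)
        probs = []
        for a, c in zip(edges[:-1], edges[1:]):
            grid = np.linspace(a, c, 50)
            f = grid**2 * np.exp(-0.5 * k * (grid - b0) ** 2)
            probs.append(np.trapezoid(f, grid))
        probs = np.asarray(probs)
        expected = probs / probs.sum() * observed.sum()
        chi2 = ((observed - expected) ** 2 / expected).sum()
        p = sps.chi2.sf(chi2, df=len(observed) - 1)
        assert p > 0.01


class TestAnnealing:
    def test_schedule_bookkeeping_reproduces_configuration_counts(self):
        schedule = AnnealSchedule()
        assert len(schedule.temperatures) == 10
        assert schedule.temperatures[0] == 400.0
        assert schedule.target_temperature == 300.0
        assert schedule.produced_at_target(200) == 2 * 10**5
        assert schedule.produced_at_target(800) == 8 * 10**5

    def test_unsorted_ladder_rejected(self):
        with pytest.raises(ValueError):
            AnnealSchedule(temperatures=(300.0, 400.0))
        with pytest.raises(ValueError):
            AnnealSchedule(temperatures=(400.0, -10.0))

    def test_annealed_run_collects_only_target_temperature_frames(self):
        system = free_chain_system(n=8)
        schedule = AnnealSchedule(
            temperatures=(400.0, 350.0, 300.0),
            configs_per_temperature=10,
            n_cycles_equilibration=1,
            n_cycles_production=4,
        )
        config = MCConfig(thinning=5, seed=3)
        ens = run_annealed(system, schedule, config)
        # 4 cycles x 10 target-T configs / thinning 5
        assert ens.n_frames == 8
        assert ens.metadata["produced_at_target"] == 40

    def test_single_temperature_ladder_degenerates_to_plain_mc(self):
        system = free_chain_system(n=8)
        schedule = AnnealSchedule(
            temperatures=(298.0,),
            configs_per_temperature=20,
            n_cycles_equilibration=1,
            n_cycles_production=2,
        )
        ens = run_annealed(system, schedule, MCConfig(thinning=10, seed=4))
        assert ens.n_frames == 4
        assert np.all(np.isfinite(ens.energies))


class TestSaltScan:
    def test_scan_keys_and_determinism(self, gluten_seq):
        config = MCConfig(
            n_equilibration_sweeps=10, n_production_sweeps=20, thinning=10, seed=5
        )
        params = EnergyModelParams()
        out = salt_scan(gluten_seq, params, [10.0, 1000.0], config)
        assert set(out) == {10.0, 1000.0}
        again = salt_scan(gluten_seq, params, [10.0, 1000.0], config)
        assert np.array_equal(out[10.0].frames, again[10.0].frames)

    def test_empty_or_invalid_salts_rejected(self, gluten_seq):
        config = MCConfig()
        with pytest.raises(ValueError):
            salt_scan(gluten_seq, EnergyModelParams(), [], config)
        with pytest.raises(ValueError):
            salt_scan(gluten_seq, EnergyModelParams(), [-10.0], config)
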