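"""Canonical-ensemble Metropolis Monte Carlo for the bead-chain model.

Move set: single-bead translation, pivot rotation, crankshaft rotation,
whole-chain translation/rotation, and counter-ion translation.  A sweep
is one attempted move per particle.  Incremental energy bookkeeping is
exact: ΔE is evaluated over the full set of pairs involving moved
particles, so unchanged pairs cancel identically and the running total
agrees with a full recomputation to floating-point accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import (
    T_REF,
    BeadChainSystem,
    EnergyModelParams,
    delta_energy,
    min_image,
    partial_energy,
    total_energy,
    write_xyz,
)

MOVE_NAMES = (
    "single_bead",
    "pivot",
    "crankshaft",
    "chain_translation",
    "chain_rotation",
    "counterion_translation",
)

DEFAULT_MOVE_MIX = {
    "single_bead": 0.45,
    "pivot": 0.20,
    "crankshaft": 0.20,
    "chain_translation": 0.03,
    "chain_rotation": 0.04,
    "counterion_translation": 0.08,
}


@dataclass
class MCConfig:
    """Sampler settings: move mix, step sizes, run lengths, seeding."""

    move_mix: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MOVE_MIX))
    single_bead_step: float = 0.5  # Å, half-width of the displacement cube
    crankshaft_max_angle: float = math.pi
    pivot_max_angle: float = math.pi
    chain_step: float = 10.0
    chain_rot_max_angle: float = math.pi
    counterion_step: float = 50.0
    n_equilibration_sweeps: int = 500
    n_production_sweeps: int = 2000
    thinning: int = 10
    seed: int = 0
    temperature_K: float = T_REF
    tune_steps: bool = True

    def __post_init__(self) -> None:
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        bad = set(self.move_mix) - set(MOVE_NAMES)
        if bad:
            raise ValueError(f"unknown move types: {sorted(bad)}")
        total = sum(self.move_mix.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError(f"move probabilities must sum to 1, got {total}")


@dataclass
class AnnealSchedule:
    """Temperature ladder for simulated annealing.

    Defaults mirror the generic protocol of the study: ten temperatures
    spanning 400→300 K, 1000 configurations per temperature per cycle,
    200 equilibration and 800 production cycles (only target-temperature
    configurations enter the returned ensemble).
    """

    temperatures: Tuple[float, ...] = tuple(np.linspace(400.0, 300.0, 10))
    configs_per_temperature: int = 1000
    n_cycles_equilibration: int = 200
    n_cycles_production: int = 800

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures)
        if np.any(t <= 0):
            raise ValueError("temperatures must be positive")
        if np.any(np.diff(t) >= 0):
            raise ValueError("temperature ladder must be strictly descending")

    @property
    def target_temperature(self) -> float:
        return float(self.temperatures[-1])

    def produced_at_target(self, n_cycles: Optional[int] = None) -> int:
        """Configurations produced at the target temperature (before thinning)."""
        cycles = self.n_cycles_production if n_cycles is None else n_cycles
        return cycles * self.configs_per_temperature


@dataclass
class Ensemble:
    """Saved configurations with per-frame scalars and run metadata."""

    frames: np.ndarray  # (F, n_chain, 3)
    ion_frames: np.ndarray  # (F, n_ions, 3)
    energies: np.ndarray  # (F,) total, k_BT(298) units
    rg: np.ndarray  # (F,) Å
    ree: np.ndarray  # (F,) Å
    acceptance: Dict[str, Tuple[int, int]]  # move -> (accepted, attempted)
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path,
            frames=self.frames,
            ion_frames=self.ion_frames,
            energies=self.energies,
            rg=self.rg,
            ree=self.ree,
            acceptance_keys=np.array(list(self.acceptance), dtype=object),
            acceptance_vals=np.array(
                [self.acceptance[k] for k in self.acceptance], dtype=int
            ),
            metadata=np.array([repr(self.metadata)], dtype=object),
        )

    @classmethod
    def load_npz(cls, path) -> "Ensemble":
        z = np.load(path, allow_pickle=True)
        keys = list(z["acceptance_keys"])
        vals = z["acceptance_vals"]
        import ast

        return cls(
            frames=z["frames"],
            ion_frames=z["ion_frames"],
            energies=z["energies"],
            rg=z["rg"],
            ree=z["ree"],
            acceptance={k: tuple(v) for k, v in zip(keys, vals)},
            metadata=ast.literal_eval(str(z["metadata"][0])),
        )

    def export_xyz(self, path, box: Optional[float] = None) -> None:
        """Per-frame XYZ trajectory (chain beads only), wrapped if box given."""
        path = Path(path)
        for k in range(self.n_frames):
            coords = self.frames[k]
            if box is not None:
                coords = coords % box
            write_xyz(path, coords, comment=f"frame {k}", append=k > 0)


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    C = 1 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def _rand_axis(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _propose(
    system: BeadChainSystem, move: str, config: MCConfig, rng: np.random.Generator
) -> Optional[Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Build trial coordinates; returns (chain, ions, moved_chain, moved_ion)."""
    n = system.n_chain
    chain = system.coords
    ions = system.ion_coords
    none_ion = np.empty(0, dtype=int)

    if move == "single_bead":
        i = int(rng.integers(n))
        new = chain.copy()
        new[i] += rng.uniform(-config.single_bead_step, config.single_bead_step, 3)
        return new, ions, np.array([i]), none_ion

    if move == "pivot":
        if n < 3:
            return None
        p = int(rng.integers(1, n - 1))
        R = _rotation_matrix(
            _rand_axis(rng), rng.uniform(-config.pivot_max_angle, config.pivot_max_angle)
        )
        new = chain.copy()
        if rng.random() < 0.5:
            seg = np.arange(p + 1, n)
        else:
            seg = np.arange(0, p)
        new[seg] = (chain[seg] - chain[p]) @ R.T + chain[p]
        return new, ions, seg, none_ion

    if move == "crankshaft":
        if n < 3:
            return None
        gap = int(rng.integers(2, min(n - 1, 12) + 1))
        i = int(rng.integers(0, n - gap))
        j = i + gap
        axis = chain[j] - chain[i]
        norm = np.linalg.norm(axis)
        if norm < 1e-12:
            return None
        R = _rotation_matrix(
            axis, rng.uniform(-config.crankshaft_max_angle, config.crankshaft_max_angle)
        )
        seg = np.arange(i + 1, j)
        new = chain.copy()
        new[seg] = (chain[seg] - chain[i]) @ R.T + chain[i]
        return new, ions, seg, none_ion

    if move == "chain_translation":
        shift = rng.uniform(-config.chain_step, config.chain_step, 3)
        return chain + shift, ions, np.arange(n), none_ion

    if move == "chain_rotation":
        R = _rotation_matrix(
            _rand_axis(rng),
            rng.uniform(-config.chain_rot_max_angle, config.chain_rot_max_angle),
        )
        centroid = chain.mean(axis=0)
        return (chain - centroid) @ R.T + centroid, ions, np.arange(n), none_ion

    if move == "counterion_translation":
        if system.n_ions == 0:
            return None
        k = int(rng.integers(system.n_ions))
        new_ions = ions.copy()
        new_ions[k] += rng.uniform(-config.counterion_step, config.counterion_step, 3)
        return chain, new_ions, np.empty(0, dtype=int), np.array([k])

    raise ValueError(f"unknown move {move!r}")


def metropolis_step(
    system: BeadChainSystem,
    move: str,
    rng: np.random.Generator,
    config: Optional[MCConfig] = None,
    temperature_K: Optional[float] = None,
) -> Tuple[BeadChainSystem, bool, float]:
    """One Metropolis trial; mutates the system in place if accepted.

    Returns (system, accepted, ΔE) with ΔE in k_BT(298) units (0 for a
    null or rejected proposal).  Hard-sphere overlap is an automatic
    rejection; acceptance probability is min(1, exp(-ΔU/k_BT)).
    """
    config = config or MCConfig()
    T = temperature_K if temperature_K is not None else config.temperature_K
    proposal = _propose(system, move, config, rng)
    if proposal is None:
        return system, False, 0.0
    new_chain, new_ions, mc, mi = proposal
    dE = delta_energy(system, new_chain, new_ions, mc, mi)
    if math.isinf(dE):
        return system, False, 0.0
    if dE <= 0 or rng.random() < math.exp(-dE * T_REF / T):
        system.coords = new_chain
        system.ion_coords = new_ions
        return system, True, dE
    return system, False, 0.0


def chain_rg(coords: np.ndarray) -> float:
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c * c).sum(axis=1).mean()))


def chain_ree(coords: np.ndarray) -> float:
    return float(np.linalg.norm(coords[-1] - coords[0]))


class _MoveStats:
    def __init__(self) -> None:
        self.accepted: Dict[str, int] = {m: 0 for m in MOVE_NAMES}
        self.attempted: Dict[str, int] = {m: 0 for m in MOVE_NAMES}

    def record(self, move: str, accepted: bool) -> None:
        self.attempted[move] += 1
        self.accepted[move] += int(accepted)

    def as_dict(self) -> Dict[str, Tuple[int, int]]:
        return {
            m: (self.accepted[m], self.attempted[m])
            for m in MOVE_NAMES
            if self.attempted[m]
        }

    def rate(self, move: str) -> float:
        a = self.attempted[move]
        return self.accepted[move] / a if a else 0.0


_TUNABLE = {
    "single_bead": "single_bead_step",
    "counterion_translation": "counterion_step",
    "chain_translation": "chain_step",
    "crankshaft": "crankshaft_max_angle",
    "pivot": "pivot_max_angle",
    "chain_rotation": "chain_rot_max_angle",
}
_STEP_CAPS = {
    "crankshaft_max_angle": math.pi,
    "pivot_max_angle": math.pi,
    "chain_rot_max_angle": math.pi,
}


def _sweep(
    system: BeadChainSystem,
    config: MCConfig,
    rng: np.random.Generator,
    moves: np.ndarray,
    probs: np.ndarray,
    stats: _MoveStats,
    temperature_K: float,
) -> None:
    cum = np.cumsum(probs)
    for _ in range(system.n_particles):
        move = moves[int(np.searchsorted(cum, rng.random()))]
        _, acc, _ = metropolis_step(system, move, rng, config, temperature_K)
        stats.record(move, acc)


def _normalized_mix(system: BeadChainSystem, config: MCConfig):
    mix = dict(config.move_mix)
    if system.n_ions == 0:
        mix.pop("counterion_translation", None)
    moves = np.array(list(mix), dtype=object)
    probs = np.array(list(mix.values()), dtype=float)
    probs /= probs.sum()
    return moves, probs


def _tune(config: MCConfig, stats: _MoveStats) -> None:
    """Nudge step sizes toward 30-50% acceptance during equilibration."""
    for move, attr in _TUNABLE.items():
        if stats.attempted[move] < 20:
            continue
        rate = stats.rate(move)
        step = getattr(config, attr)
        if rate > 0.5:
            step *= 1.25
        elif rate < 0.3:
            step *= 0.8
        setattr(config, attr, min(step, _STEP_CAPS.get(attr, 200.0)))


def run_mc(system: BeadChainSystem, config: MCConfig) -> Ensemble:
    """Equilibrate (with step tuning), then sample a thinned ensemble.

    One configuration is produced per sweep; every ``thinning``-th is
    saved, so the ensemble holds floor(production/thinning) frames.
    Bitwise reproducible for a fixed seed and config.
    """
    if config.n_production_sweeps < 1:
        raise ValueError("n_production_sweeps must be >= 1")
    rng = np.random.default_rng(config.seed)
    config = replace(config, move_mix=dict(config.move_mix))
    moves, probs = _normalized_mix(system, config)
    T = config.temperature_K

    stats = _MoveStats()
    for sweep_i in range(config.n_equilibration_sweeps):
        _sweep(system, config, rng, moves, probs, stats, T)
        if config.tune_steps and (sweep_i + 1) % 50 == 0:
            _tune(config, stats)
            stats = _MoveStats()

    stats = _MoveStats()
    e_run = total_energy(system).total
    cum = np.cumsum(probs)
    frames, ion_frames, energies, rgs, rees = [], [], [], [], []
    for sweep_i in range(1, config.n_production_sweeps + 1):
        for _ in range(system.n_particles):
            move = moves[int(np.searchsorted(cum, rng.random()))]
            _, acc, dE = metropolis_step(system, move, rng, config, T)
            stats.record(move, acc)
            e_run += dE
        if sweep_i % config.thinning == 0:
            frames.append(system.coords.copy())
            ion_frames.append(system.ion_coords.copy())
            energies.append(e_run)
            rgs.append(chain_rg(system.coords))
            rees.append(chain_ree(system.coords))
    if not frames:
        raise ValueError(
            "no frames saved: production sweeps shorter than thinning interval"
        )
    drift = abs(e_run - total_energy(system).total)
    return Ensemble(
        frames=np.array(frames),
        ion_frames=np.array(ion_frames),
        energies=np.array(energies),
        rg=np.array(rgs),
        ree=np.array(rees),
        acceptance=stats.as_dict(),
        metadata={
            "seed": config.seed,
            "temperature_K": T,
            "salt_mM": system.params.salt_mM,
            "n_equilibration_sweeps": config.n_equilibration_sweeps,
            "n_production_sweeps": config.n_production_sweeps,
            "thinning": config.thinning,
            "energy_drift_kT": float(drift),
            "restrained": bool(system.restraints),
        },
    )


def run_annealed(
    system: BeadChainSystem, schedule: AnnealSchedule, config: MCConfig
) -> Ensemble:
    """Cycle through the temperature ladder; sample only at the target T.

    Each cycle visits every ladder temperature in descending order and
    produces ``configs_per_temperature`` configurations (sweeps) at
    each; target-temperature production configurations are saved with
    the configured thinning.  Equilibration cycles are discarded.
    """
    rng = np.random.default_rng(config.seed)
    config = replace(config, move_mix=dict(config.move_mix))
    moves, probs = _normalized_mix(system, config)
    target = schedule.target_temperature

    def cycle(collect: bool, stats: _MoveStats, sink=None) -> None:
        for T in schedule.temperatures:
            for k in range(1, schedule.configs_per_temperature + 1):
                _sweep(system, config, rng, moves, probs, stats, T)
                if collect and T == target and k % config.thinning == 0:
                    sink.append(
                        (system.coords.copy(), system.ion_coords.copy())
                    )

    stats = _MoveStats()
    for _ in range(schedule.n_cycles_equilibration):
        cycle(False, stats)
    stats = _MoveStats()
    saved: List[Tuple[np.ndarray, np.ndarray]] = []
    for _ in range(schedule.n_cycles_production):
        cycle(True, stats, saved)
    frames = np.array([s[0] for s in saved])
    ion_frames = np.array([s[1] for s in saved])
    sys2 = system.copy()
    e_list, rg_list, ree_list = [], [], []
    for chain, ions in saved:
        sys2.coords, sys2.ion_coords = chain, ions
        e_list.append(total_energy(sys2).total)
        rg_list.append(chain_rg(chain))
        ree_list.append(chain_ree(chain))
    return Ensemble(
        frames=frames,
        ion_frames=ion_frames,
        energies=np.array(e_list),
        rg=np.array(rg_list),
        ree=np.array(ree_list),
        acceptance=stats.as_dict(),
        metadata={
            "seed": config.seed,
            "schedule_temperatures": [float(t) for t in schedule.temperatures],
            "configs_per_temperature": schedule.configs_per_temperature,
            "n_cycles_production": schedule.n_cycles_production,
            "produced_at_target": schedule.produced_at_target(),
            "thinning": config.thinning,
            "salt_mM": system.params.salt_mM,
        },
    )


def salt_scan(
    seq,
    params: EnergyModelParams,
    salts: Sequence[float],
    config: MCConfig,
    scheme=None,
    restraint_pairs: Sequence[Tuple[int, int]] = (),
) -> Dict[float, Ensemble]:
    """Independent simulations across a salt series (default 10/80/500/1000 mM).

    Child seeds are derived deterministically from the master seed via
    a spawned SeedSequence per salt; the derivation is recorded in each
    ensemble's metadata.
    """
    from .model import build_system

    if not len(salts):
        raise ValueError("salt list must be non-empty")
    if any(s <= 0 for s in salts):
        raise ValueError("salt concentrations must be positive")
    children = np.random.SeedSequence(config.seed).spawn(len(salts))
    out: Dict[float, Ensemble] = {}
    for k, salt in enumerate(salts):
        child_seed = int(children[k].generate_state(1)[0] % (2**31))
        p = replace(params, salt_mM=float(salt))
        system = build_system(
            seq, p, scheme=scheme, restraint_pairs=restraint_pairs, seed=child_seed
        )
        cfg = replace(config, seed=child_seed, move_mix=dict(config.move_mix))
        ens = run_mc(system, cfg)
        ens.metadata["master_seed"] = config.seed
        ens.metadata["salt_index"] = k
        out[float(salt)] = ens
    return out
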