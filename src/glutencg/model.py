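"""Coarse-grained bead-chain model with screened electrostatics.

One bead per mature residue, charged or neutral according to the charge
scheme, in a periodic cubic box with explicit monovalent counter-ions
added for electroneutrality.  Interactions: harmonic bonds between
consecutive beads, hard-sphere excluded volume, an extended
Debye–Hückel potential between all charge pairs (salt implicit,
counter-ions explicit), and stiff harmonic restraints standing in for
disulfide bonds.  All energies are expressed in units of k_BT at the
reference temperature 298 K; simulated annealing rescales them by
T_ref/T in the acceptance rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .scales import ResidueScaleTable, charge_scheme
from .sequence_io import ProteinSequence

T_REF = 298.0  # K; energy unit is k_B * T_REF


@dataclass(frozen=True)
class EnergyModelParams:
    """Physical parameters of the bead-chain energy model.

    Lengths in Å; force constants in k_BT(298 K)/Å².  The Debye length
    is derived from the 1:1 salt molarity as 3.04/sqrt(c[M]) Å unless
    overridden explicitly (``debye_length_override=inf`` gives the
    unscreened Coulomb limit).
    """

    bead_radius: float = 2.0
    bond_length: float = 4.1
    bond_force_constant: float = 30.0  # <5% relative bond fluctuation at 298 K
    bjerrum_length: float = 7.14
    temperature: float = 298.0
    box_length: float = 1500.0
    salt_mM: float = 80.0
    restraint_force_constant: float = 10.0
    restraint_target: float = 4.0  # bead-centre contact distance
    debye_length_override: Optional[float] = None

    @property
    def debye_length(self) -> float:
        if self.debye_length_override is not None:
            return self.debye_length_override
        if self.salt_mM <= 0:
            raise ValueError("salt_mM must be positive (or override the Debye length)")
        return 3.04 / math.sqrt(self.salt_mM / 1000.0)

    def to_dict(self) -> dict:
        return {
            "bead_radius": self.bead_radius,
            "bond_length": self.bond_length,
            "bond_force_constant": self.bond_force_constant,
            "bjerrum_length": self.bjerrum_length,
            "temperature": self.temperature,
            "box_length": self.box_length,
            "salt_mM": self.salt_mM,
            "restraint_force_constant": self.restraint_force_constant,
            "restraint_target": self.restraint_target,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnergyModelParams":
        return cls(**d)


@dataclass(frozen=True)
class DisulfideRestraint:
    """Permanent harmonic restraint between two cysteine beads.

    Indices are 1-based on the mature sequence.  The target is a
    bead-centre contact distance: with 2 Å beads the experimental ~2 Å
    S–S separation is geometrically forbidden between centres, so the
    default keeps the pair in permanent contact instead.
    """

    residue_i: int
    residue_j: int
    target_distance: float = 4.0
    force_constant: float = 10.0

    def __post_init__(self) -> None:
        if not self.residue_i < self.residue_j:
            raise ValueError("restraint indices must satisfy i < j")


@dataclass
class EnergyBreakdown:
    bond: float = 0.0
    excluded_volume: float = 0.0
    electrostatic: float = 0.0
    restraint: float = 0.0

    @property
    def total(self) -> float:
        return self.bond + self.excluded_volume + self.electrostatic + self.restraint


def min_image(d: np.ndarray, box: float) -> np.ndarray:
    """Minimum-image displacement components for a cubic box."""
    return d - box * np.round(d / box)


def _mi_dist(a: np.ndarray, b: np.ndarray, box: float) -> np.ndarray:
    """Pairwise minimum-image distances, shape (len(a), len(b))."""
    d = min_image(a[:, None, :] - b[None, :, :], box)
    return np.sqrt((d * d).sum(axis=2))


def pair_electrostatic(r, z_i, z_j, params: EnergyModelParams):
    """Extended Debye–Hückel pair energy in k_BT units.

    u/k_BT = z_i z_j l_B/r · exp(-(r-σ)/λ_D) / (1 + σ/(2 λ_D)),
    with σ = 2·bead_radius the contact distance.  Vectorized over r.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    zz = np.asarray(z_i) * np.asarray(z_j)
    sigma = 2.0 * params.bead_radius
    lam = params.debye_length
    if math.isinf(lam):
        u = zz * params.bjerrum_length / r
    else:
        u = (
            zz
            * params.bjerrum_length
            / r
            * np.exp(-(r - sigma) / lam)
            / (1.0 + sigma / (2.0 * lam))
        )
    return u if u.shape else float(u)


@dataclass
class BeadChainSystem:
    """Mutable simulation state: chain beads, counter-ions, restraints."""

    coords: np.ndarray  # (n_chain, 3), Å, unwrapped
    charges: np.ndarray  # (n_chain,), integer elementary charges
    ion_coords: np.ndarray  # (n_ions, 3)
    ion_charges: np.ndarray  # (n_ions,)
    restraints: List[DisulfideRestraint]
    params: EnergyModelParams
    sequence: Optional[ProteinSequence] = None

    @property
    def n_chain(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_ions(self) -> int:
        return int(self.ion_coords.shape[0])

    @property
    def n_particles(self) -> int:
        return self.n_chain + self.n_ions

    def all_coords(self) -> np.ndarray:
        return np.vstack([self.coords, self.ion_coords]) if self.n_ions else self.coords

    def all_charges(self) -> np.ndarray:
        return (
            np.concatenate([self.charges, self.ion_charges])
            if self.n_ions
            else self.charges
        )

    def is_electroneutral(self) -> bool:
        return int(self.charges.sum() + self.ion_charges.sum()) == 0

    def copy(self) -> "BeadChainSystem":
        return BeadChainSystem(
            coords=self.coords.copy(),
            charges=self.charges.copy(),
            ion_coords=self.ion_coords.copy(),
            ion_charges=self.ion_charges.copy(),
            restraints=list(self.restraints),
            params=self.params,
            sequence=self.sequence,
        )


def build_system(
    seq: ProteinSequence,
    params: EnergyModelParams = EnergyModelParams(),
    scheme: Optional[ResidueScaleTable] = None,
    restraint_pairs: Sequence[Tuple[int, int]] = (),
    seed: int = 0,
) -> BeadChainSystem:
    """Assemble a bead-chain system from a mature sequence.

    The initial chain conformation is a hard-sphere self-avoiding
    configuration centred in the box; |net charge| monovalent
    counter-ions of opposite sign are placed uniformly at random
    without overlaps, giving an electroneutral system.
    """
    from .synthetic import generate_saw_chain  # deferred: avoids import cycle

    scheme = scheme or charge_scheme()
    rng = np.random.default_rng(seed)
    cys = set(seq.cys_positions)
    restraints = []
    for i, j in restraint_pairs:
        if i not in cys or j not in cys:
            raise ValueError(
                f"restraint pair ({i}, {j}) does not reference two cysteines "
                f"(cys positions: {sorted(cys)})"
            )
        restraints.append(
            DisulfideRestraint(
                residue_i=min(i, j),
                residue_j=max(i, j),
                target_distance=params.restraint_target,
                force_constant=params.restraint_force_constant,
            )
        )

    n = len(seq)
    charges = np.array([int(scheme[c]) for c in seq.residues])
    contour = (n - 1) * params.bond_length
    if params.box_length < 2 * contour:
        warnings.warn(
            f"box length {params.box_length} Å is less than twice the contour "
            f"length {contour:.0f} Å; periodic self-images may interact"
        )
    conf = generate_saw_chain(n, params.bond_length, params.bead_radius, rng)
    coords = conf.coordinates - conf.coordinates.mean(axis=0) + params.box_length / 2

    net = int(charges.sum())
    n_ions = abs(net)
    ion_charges = np.full(n_ions, -np.sign(net), dtype=int)
    ion_coords = np.empty((0, 3))
    if n_ions:
        placed: List[np.ndarray] = []
        sigma = 2 * params.bead_radius
        for _ in range(n_ions):
            for _attempt in range(10000):
                trial = rng.uniform(0, params.box_length, size=3)
                others = np.vstack([coords] + [p[None] for p in placed])
                if _mi_dist(trial[None], others, params.box_length).min() >= sigma:
                    placed.append(trial)
                    break
            else:
                raise RuntimeError("box too crowded to place counter-ions")
        ion_coords = np.array(placed)

    return BeadChainSystem(
        coords=coords,
        charges=charges,
        ion_coords=ion_coords,
        ion_charges=ion_charges,
        restraints=restraints,
        params=params,
        sequence=seq,
    )


def _electro_cross(
    a: np.ndarray, qa: np.ndarray, b: np.ndarray, qb: np.ndarray,
    params: EnergyModelParams,
) -> float:
    """Screened-Coulomb energy of all pairs between two disjoint sets."""
    ia = np.nonzero(qa)[0]
    ib = np.nonzero(qb)[0]
    if len(ia) == 0 or len(ib) == 0:
        return 0.0
    r = _mi_dist(a[ia], b[ib], params.box_length).clip(min=1e-12)
    zz = np.outer(qa[ia], qb[ib])
    return float(np.sum(pair_electrostatic(r, 1, 1, params) * zz))


def _electro_within(
    a: np.ndarray, qa: np.ndarray, params: EnergyModelParams
) -> float:
    idx = np.nonzero(qa)[0]
    if len(idx) < 2:
        return 0.0
    r = _mi_dist(a[idx], a[idx], params.box_length)
    zz = np.outer(qa[idx], qa[idx])
    iu = np.triu_indices(len(idx), k=1)
    return float(np.sum(pair_electrostatic(r[iu].clip(min=1e-12), 1, 1, params) * zz[iu]))


def total_energy(system: BeadChainSystem) -> EnergyBreakdown:
    """Full energy breakdown in k_BT(298 K) units.

    Hard-sphere overlaps are flagged as an infinite excluded-volume term.
    """
    p = system.params
    X = system.all_coords()
    q = system.all_charges()
    out = EnergyBreakdown()

    # excluded volume: any pair closer than contact
    r = _mi_dist(X, X, p.box_length)
    iu = np.triu_indices(len(X), k=1)
    if np.any(r[iu] < 2 * p.bead_radius):
        out.excluded_volume = math.inf

    # bonds
    d = np.linalg.norm(
        min_image(system.coords[1:] - system.coords[:-1], p.box_length), axis=1
    )
    out.bond = float(0.5 * p.bond_force_constant * np.sum((d - p.bond_length) ** 2))

    # electrostatics (all charge pairs, minimum image)
    out.electrostatic = _electro_within(X, q, p)

    # restraints
    e_r = 0.0
    for rest in system.restraints:
        rij = np.linalg.norm(
            min_image(
                system.coords[rest.residue_j - 1] - system.coords[rest.residue_i - 1],
                p.box_length,
            )
        )
        e_r += 0.5 * rest.force_constant * (rij - rest.target_distance) ** 2
    out.restraint = e_r
    return out


def partial_energy(
    system: BeadChainSystem,
    chain_coords: np.ndarray,
    ion_coords: np.ndarray,
    moved_chain: np.ndarray,
    moved_ion: np.ndarray,
) -> float:
    """Energy of all terms involving the moved particles.

    Evaluated on candidate coordinates; the same pair set before and
    after a move yields an exact ΔE (unchanged pairs cancel).  Returns
    +inf on hard-sphere overlap involving a moved particle.
    """
    p = system.params
    n = system.n_chain
    X = np.vstack([chain_coords, ion_coords]) if len(ion_coords) else chain_coords
    q = system.all_charges()
    moved = np.concatenate([moved_chain, moved_ion + n]).astype(int)
    mask = np.zeros(len(X), dtype=bool)
    mask[moved] = True
    A, qa = X[mask], q[mask]
    B, qb = X[~mask], q[~mask]

    # overlap checks
    sigma = 2 * p.bead_radius
    if len(B) and _mi_dist(A, B, p.box_length).min() < sigma:
        return math.inf
    if len(A) > 1:
        r = _mi_dist(A, A, p.box_length)
        iu = np.triu_indices(len(A), k=1)
        if r[iu].min() < sigma:
            return math.inf

    e = _electro_cross(A, qa, B, qb, p) + _electro_within(A, qa, p)

    # bonds touching a moved chain bead
    if n > 1 and len(moved_chain):
        touched = set()
        for i in moved_chain:
            if i > 0:
                touched.add(i - 1)
            if i < n - 1:
                touched.add(int(i))
        bi = np.array(sorted(touched), dtype=int)
        d = np.linalg.norm(
            min_image(chain_coords[bi + 1] - chain_coords[bi], p.box_length), axis=1
        )
        e += float(0.5 * p.bond_force_constant * np.sum((d - p.bond_length) ** 2))

    moved_set = set(int(i) for i in moved_chain)
    for rest in system.restraints:
        if (rest.residue_i - 1) in moved_set or (rest.residue_j - 1) in moved_set:
            rij = np.linalg.norm(
                min_image(
                    chain_coords[rest.residue_j - 1] - chain_coords[rest.residue_i - 1],
                    p.box_length,
                )
            )
            e += 0.5 * rest.force_constant * (rij - rest.target_distance) ** 2
    return e


try:  # compiled ΔE kernel; the numpy path below is the reference fallback
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _delta_energy_kernel(
    old, new, is_moved, moved, charges, n_chain,
    box, sigma, l_b, lam, screened,
    bond_k, bond_b0, rest_i, rest_j, rest_k, rest_r0,
):  # pragma: no cover - exercised via metropolis_step
    pref = l_b / (1.0 + sigma / (2.0 * lam)) if screened else l_b
    e_old = 0.0
    e_new = 0.0
    n = old.shape[0]
    for a in range(moved.shape[0]):
        i = moved[a]
        zi = charges[i]
        for j in range(n):
            if j == i or (is_moved[j] and j <= i):
                continue
            dx = new[i, 0] - new[j, 0]
            dy = new[i, 1] - new[j, 1]
            dz = new[i, 2] - new[j, 2]
            dx -= box * np.round(dx / box)
            dy -= box * np.round(dy / box)
            dz -= box * np.round(dz / box)
            r_new = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r_new < sigma:
                return np.inf
            zz = zi * charges[j]
            if zz != 0:
                dx = old[i, 0] - old[j, 0]
                dy = old[i, 1] - old[j, 1]
                dz = old[i, 2] - old[j, 2]
                dx -= box * np.round(dx / box)
                dy -= box * np.round(dy / box)
                dz -= box * np.round(dz / box)
                r_old = np.sqrt(dx * dx + dy * dy + dz * dz)
                if screened:
                    e_old += zz * pref / r_old * np.exp(-(r_old - sigma) / lam)
                    e_new += zz * pref / r_new * np.exp(-(r_new - sigma) / lam)
                else:
                    e_old += zz * pref / r_old
                    e_new += zz * pref / r_new
    for a in range(n_chain - 1):
        if is_moved[a] or is_moved[a + 1]:
            dx = old[a, 0] - old[a + 1, 0]
            dy = old[a, 1] - old[a + 1, 1]
            dz = old[a, 2] - old[a + 1, 2]
            dx -= box * np.round(dx / box)
            dy -= box * np.round(dy / box)
            dz -= box * np.round(dz / box)
            d = np.sqrt(dx * dx + dy * dy + dz * dz) - bond_b0
            e_old += 0.5 * bond_k * d * d
            dx = new[a, 0] - new[a + 1, 0]
            dy = new[a, 1] - new[a + 1, 1]
            dz = new[a, 2] - new[a + 1, 2]
            dx -= box * np.round(dx / box)
            dy -= box * np.round(dy / box)
            dz -= box * np.round(dz / box)
            d = np.sqrt(dx * dx + dy * dy + dz * dz) - bond_b0
            e_new += 0.5 * bond_k * d * d
    for t in range(rest_i.shape[0]):
        i = rest_i[t]
        j = rest_j[t]
        if is_moved[i] or is_moved[j]:
            dx = old[i, 0] - old[j, 0]
            dy = old[i, 1] - old[j, 1]
            dz = old[i, 2] - old[j, 2]
            dx -= box * np.round(dx / box)
            dy -= box * np.round(dy / box)
            dz -= box * np.round(dz / box)
            d = np.sqrt(dx * dx + dy * dy + dz * dz) - rest_r0[t]
            e_old += 0.5 * rest_k[t] * d * d
            dx = new[i, 0] - new[j, 0]
            dy = new[i, 1] - new[j, 1]
            dz = new[i, 2] - new[j, 2]
            dx -= box * np.round(dx / box)
            dy -= box * np.round(dy / box)
            dz -= box * np.round(dz / box)
            d = np.sqrt(dx * dx + dy * dy + dz * dz) - rest_r0[t]
            e_new += 0.5 * rest_k[t] * d * d
    return e_new - e_old


def delta_energy(
    system: "BeadChainSystem",
    new_chain: np.ndarray,
    new_ions: np.ndarray,
    moved_chain: np.ndarray,
    moved_ion: np.ndarray,
) -> float:
    """Exact ΔE of a trial move; +inf on hard-sphere overlap."""
    p = system.params
    n = system.n_chain
    old = system.all_coords()
    new = np.vstack([new_chain, new_ions]) if len(new_ions) else new_chain
    moved = np.concatenate([moved_chain, moved_ion + n]).astype(np.int64)
    if _HAVE_NUMBA:
        is_moved = np.zeros(len(old), dtype=np.bool_)
        is_moved[moved] = True
        rest_i = np.array([r.residue_i - 1 for r in system.restraints], dtype=np.int64)
        rest_j = np.array([r.residue_j - 1 for r in system.restraints], dtype=np.int64)
        rest_k = np.array([r.force_constant for r in system.restraints])
        rest_r0 = np.array([r.target_distance for r in system.restraints])
        lam = p.debye_length
        screened = not math.isinf(lam)
        return float(
            _delta_energy_kernel(
                old, new, is_moved, moved,
                system.all_charges().astype(np.float64), n,
                p.box_length, 2.0 * p.bead_radius, p.bjerrum_length,
                lam if screened else 1.0, screened,
                p.bond_force_constant, p.bond_length,
                rest_i, rest_j, rest_k, rest_r0,
            )
        )
    e_new = partial_energy(system, new_chain, new_ions, moved_chain, moved_ion)
    if math.isinf(e_new):
        return math.inf
    e_old = partial_energy(
        system, system.coords, system.ion_coords, moved_chain, moved_ion
    )
    return e_new - e_old


def write_xyz(path, coords: np.ndarray, charges: Optional[np.ndarray] = None,
              comment: str = "", append: bool = False) -> None:
    """XYZ snapshot; the element column carries the bead charge sign."""
    symbols = ["N0"] * len(coords)
    if charges is not None:
        symbols = ["P1" if z > 0 else "M1" if z < 0 else "N0" for z in charges]
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write(f"{len(coords)}\n{comment}\n")
        for s, (x, y, z) in zip(symbols, coords):
            fh.write(f"{s} {x:.4f} {y:.4f} {z:.4f}\n")
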