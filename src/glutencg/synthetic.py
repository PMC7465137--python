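"""Synthetic gluten-like sequences and reference polymer conformations.

Wheat prolamins have a proline/glutamine-rich repetitive N-terminal
domain, 6–8 cysteines embedded in hydrophobic or hydrophilic sequence
context, and a low charge fraction (net charge +1 to +7 over ~250–290
residues).  :func:`generate_gluten_like_sequence` emulates exactly that
statistical structure so the whole pipeline is testable without any
database download.  The conformation generators provide the analytic
reference shapes (rod, freely-jointed/ideal chain, hard-sphere
self-avoiding walk) against which shape factors and Flory exponents are
anchored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .scales import KYTE_DOOLITTLE_VALUES
from .sequence_io import ProteinSequence

# Flank pools with strictly positive / strictly negative Kyte-Doolittle
# values, so a window-15 profile centred on the cysteine has a guaranteed
# sign (C itself is +2.5).
_HYDROPHOBIC_POOL = "IVLF"
_HYDROPHILIC_POOL = "SNQT"
_FILLER_POOL = "QPSGT"
_FLANK = 7  # residues per side; covers the half-window of a 15-window profile

DEFAULT_MOTIFS = ("PQQPFPQ", "PQQPQQPFPQQP")


class FeasibilityError(ValueError):
    """Requested sequence composition does not fit the target length."""


@dataclass(frozen=True)
class GlutenSequenceParams:
    """Composition targets for a synthetic gluten-like sequence."""

    total_length: int = 265
    n_repeat_motifs: int = 10
    motif_alphabet: Tuple[str, ...] = DEFAULT_MOTIFS
    n_cys_hydrophobic: int = 6
    n_cys_hydrophilic: int = 2
    target_net_charge: int = 1
    n_negative: int = 6
    seed: int = 0


def generate_gluten_like_sequence(params: GlutenSequenceParams) -> ProteinSequence:
    """Deterministically build a gluten-like sequence from composition targets.

    The sequence is a P/Q-rich repeat domain followed by a C-terminal
    domain carrying the cysteines (each wrapped in 7 residues of
    uniformly hydrophobic or hydrophilic context per side), the charged
    residues, and neutral filler.  For a fixed seed the output is
    reproducible; the realized length, cysteine count, cysteine contexts
    and net charge (default charge scheme) match the parameters exactly.
    """
    rng = np.random.default_rng(params.seed)
    if params.n_negative < 0:
        raise FeasibilityError("n_negative must be non-negative")
    n_pos = params.n_negative + params.target_net_charge
    if n_pos < 0:
        raise FeasibilityError(
            f"target net charge {params.target_net_charge} needs at least "
            f"{-params.target_net_charge} negative residues"
        )
    for motif in params.motif_alphabet:
        if set(motif) & set("CKRDEH"):
            raise FeasibilityError(
                f"repeat motif {motif!r} must not contain Cys, His or "
                "charged residues"
            )

    repeat = "".join(
        params.motif_alphabet[rng.integers(len(params.motif_alphabet))]
        for _ in range(params.n_repeat_motifs)
    )
    n_cys = params.n_cys_hydrophobic + params.n_cys_hydrophilic
    block_len = 2 * _FLANK + 1
    n_charged = n_pos + params.n_negative
    rem = params.total_length - len(repeat) - n_cys * block_len - n_charged
    if rem < 0:
        raise FeasibilityError(
            f"total_length {params.total_length} too short for "
            f"{len(repeat)} repeat residues + {n_cys} cysteine blocks "
            f"({n_cys * block_len} aa) + {n_charged} charged residues"
        )

    def block(pool: str) -> str:
        flanks = rng.choice(list(pool), size=2 * _FLANK)
        return "".join(flanks[:_FLANK]) + "C" + "".join(flanks[_FLANK:])

    blocks = [block(_HYDROPHOBIC_POOL) for _ in range(params.n_cys_hydrophobic)]
    blocks += [block(_HYDROPHILIC_POOL) for _ in range(params.n_cys_hydrophilic)]
    rng.shuffle(blocks)

    loose = list("K" * n_pos + "E" * params.n_negative) + [
        _FILLER_POOL[i] for i in rng.integers(len(_FILLER_POOL), size=rem)
    ]
    rng.shuffle(loose)

    # interleave cysteine blocks evenly through the loose C-terminal residues
    tail_parts: List[str] = []
    cuts = np.linspace(0, len(loose), n_cys + 1).astype(int)
    for k in range(n_cys):
        tail_parts.append("".join(loose[cuts[k]:cuts[k + 1]]))
        tail_parts.append(blocks[k])
    tail_parts.append("".join(loose[cuts[n_cys]:]) if n_cys else "".join(loose))
    residues = repeat + "".join(tail_parts)
    assert len(residues) == params.total_length
    return ProteinSequence(id=f"synthetic_gluten_seed{params.seed}", residues=residues)


@dataclass(frozen=True)
class ReferenceConformation:
    """A single chain conformation with known generating statistics."""

    kind: str  # rod | ideal_chain | saw_chain
    bond_length: float
    coordinates: np.ndarray  # (n_beads, 3), Å

    @property
    def n_beads(self) -> int:
        return int(self.coordinates.shape[0])


def generate_rod(n: int, b: float) -> ReferenceConformation:
    """Collinear equally spaced beads along z."""
    if n < 2:
        raise ValueError("a rod needs at least 2 beads")
    if b <= 0:
        raise ValueError("bond length must be positive")
    coords = np.zeros((n, 3))
    coords[:, 2] = b * np.arange(n)
    return ReferenceConformation("rod", b, coords)


def _random_unit_vectors(rng: np.random.Generator, m: int) -> np.ndarray:
    v = rng.normal(size=(m, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def generate_ideal_chain(
    n: int, b: float = 1.0, seed: int | np.random.Generator = 0
) -> ReferenceConformation:
    """Freely-jointed chain: independent uniform bond directions."""
    if n < 2:
        raise ValueError("a chain needs at least 2 beads")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bonds = b * _random_unit_vectors(rng, n - 1)
    coords = np.vstack([np.zeros(3), np.cumsum(bonds, axis=0)])
    return ReferenceConformation("ideal_chain", b, coords)


def generate_ideal_ensemble(
    n: int, b: float = 1.0, n_chains: int = 1000, seed: int = 0
) -> np.ndarray:
    """Vectorized ensemble of freely-jointed chains, shape (n_chains, n, 3)."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_chains, n - 1, 3))
    v *= b / np.linalg.norm(v, axis=2, keepdims=True)
    coords = np.zeros((n_chains, n, 3))
    coords[:, 1:] = np.cumsum(v, axis=1)
    return coords


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def _pivot_once(
    coords: np.ndarray, radius: float, rng: np.random.Generator
) -> Optional[np.ndarray]:
    """Attempt one pivot move; return new coordinates or None if rejected."""
    n = coords.shape[0]
    p = int(rng.integers(1, n - 1))
    R = _rotation_matrix(_random_unit_vectors(rng, 1)[0], rng.uniform(0, 2 * np.pi))
    head, pivot, tail = coords[:p], coords[p], coords[p + 1:]
    new_tail = (tail - pivot) @ R.T + pivot
    # intra-head and intra-tail distances are preserved by the rigid move;
    # only cross distances can create overlaps
    if cdist(np.vstack([head, pivot[None]]), new_tail).min() < 2 * radius:
        return None
    out = coords.copy()
    out[p + 1:] = new_tail
    return out


def generate_saw_chain(
    n: int,
    b: float = 1.0,
    radius: float = 0.4,
    seed: int | np.random.Generator = 0,
    n_equil_accepted: Optional[int] = None,
) -> ReferenceConformation:
    """Hard-sphere self-avoiding chain via the pivot algorithm.

    Starts from a rod and discards ``n_equil_accepted`` (default 10·n)
    accepted pivot moves before returning a configuration.
    """
    if radius >= b / 2:
        raise ValueError(
            f"bead radius {radius} must be < half the bond length {b / 2}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    target = 10 * n if n_equil_accepted is None else n_equil_accepted
    coords = generate_rod(n, b).coordinates.copy()
    accepted = 0
    while accepted < target:
        trial = _pivot_once(coords, radius, rng)
        if trial is not None:
            coords = trial
            accepted += 1
    return ReferenceConformation("saw_chain", b, coords)


def generate_saw_ensemble(
    n: int,
    b: float = 1.0,
    radius: float = 0.4,
    n_samples: int = 200,
    spacing_accepted: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Sample SAW configurations from one pivot Markov chain.

    Returns shape (n_samples, n, 3); samples are ``spacing_accepted``
    accepted pivots apart after a 10·n accepted-move equilibration.
    """
    rng = np.random.default_rng(seed)
    conf = generate_saw_chain(n, b, radius, rng)
    coords = conf.coordinates
    out = np.empty((n_samples, n, 3))
    for i in range(n_samples):
        accepted = 0
        while accepted < spacing_accepted:
            trial = _pivot_once(coords, radius, rng)
            if trial is not None:
                coords = trial
                accepted += 1
        out[i] = coords
    return out


def min_pairwise_distance(coords: np.ndarray) -> float:
    return float(pdist(coords).min())
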