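"""Ensemble observables: size, shape, scaling, scattering, contacts.

Implements the quantities used to characterize disordered-protein
ensembles: radius of gyration and its distribution, the shape factor
R_shape = ⟨Ree²⟩/⟨Rg²⟩ (≈1 globule, ≈6 random walk, ≈12 rod), the Flory
exponent ν from Rg ∝ R0·N^ν, orientation-averaged Debye scattering with
dimensionless Kratky representation, residue contact maps, and cysteine
contact networks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


def _frames(ensemble) -> np.ndarray:
    """Accept an Ensemble, an (F, n, 3) array, or a single (n, 3) frame."""
    if hasattr(ensemble, "frames"):
        return np.asarray(ensemble.frames)
    a = np.asarray(ensemble, dtype=float)
    if a.ndim == 2:
        a = a[None]
    if a.ndim != 3 or a.shape[2] != 3:
        raise ValueError(f"expected (F, n, 3) coordinates, got shape {a.shape}")
    return a


def radius_of_gyration(configuration) -> float:
    """RMS distance of beads from their centroid (unit masses), Å."""
    coords = np.asarray(
        getattr(configuration, "coordinates", configuration), dtype=float
    )
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("configuration must contain at least one bead")
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c * c).sum(axis=1).mean()))


def end_to_end_distance(configuration) -> float:
    coords = np.asarray(
        getattr(configuration, "coordinates", configuration), dtype=float
    )
    return float(np.linalg.norm(coords[-1] - coords[0]))


@dataclass(frozen=True)
class ShapeStats:
    """Ensemble size/shape summary."""

    mean_rg: float
    var_rg: float
    mean_sq_rg: float
    mean_sq_ree: float
    n_beads: int
    r0: float = 2.0

    @property
    def r_shape(self) -> float:
        return self.mean_sq_ree / self.mean_sq_rg

    @property
    def nu(self) -> float:
        """Flory exponent from the ensemble mean Rg in single-point mode."""
        return flory_fit((self.mean_rg, self.n_beads), r0=self.r0)

    def to_dict(self) -> dict:
        return {
            "mean_Rg": self.mean_rg,
            "var_Rg": self.var_rg,
            "mean_sq_Rg": self.mean_sq_rg,
            "mean_sq_Ree": self.mean_sq_ree,
            "R_shape": self.r_shape,
            "nu": self.nu,
            "R0": self.r0,
            "N": self.n_beads,
        }


def shape_factor(ensemble, r0: float = 2.0) -> ShapeStats:
    """⟨Ree²⟩/⟨Rg²⟩ and companions; Ree is first-to-last chain bead."""
    frames = _frames(ensemble)
    if frames.shape[1] < 2:
        raise ValueError("shape factor undefined for single-bead chains")
    rg = np.array([radius_of_gyration(f) for f in frames])
    ree = np.linalg.norm(frames[:, -1] - frames[:, 0], axis=1)
    return ShapeStats(
        mean_rg=float(rg.mean()),
        var_rg=float(rg.var()),
        mean_sq_rg=float((rg**2).mean()),
        mean_sq_ree=float((ree**2).mean()),
        n_beads=int(frames.shape[1]),
        r0=r0,
    )


PointData = Tuple[float, int]
SeriesData = Sequence[Tuple[int, float]]


def flory_fit(
    data: Union[PointData, SeriesData],
    r0: float = 2.0,
    fix_prefactor: bool = False,
) -> float:
    """Flory exponent ν from Rg = R0·N^ν.

    Single-point mode (``data = (mean_rg, N)``): ν = ln(Rg/R0)/ln(N).
    Regression mode (``data = [(N, mean_rg), ...]``, ≥3 distinct N):
    least-squares slope of ln Rg vs ln N; with ``fix_prefactor`` the
    intercept is pinned at ln R0, otherwise it is free (the exponent is
    then independent of the chain model's own prefactor).  A non-positive
    ν is returned with a warning rather than an error.
    """
    first = data[0]
    if np.isscalar(first):
        rg, n = float(data[0]), int(data[1])
        if rg <= 0 or n < 2:
            raise ValueError("need Rg > 0 and N >= 2")
        nu = np.log(rg / r0) / np.log(n)
    else:
        pairs = [(int(n), float(rg)) for n, rg in data]
        if len({n for n, _ in pairs}) < 3:
            raise ValueError("regression mode needs >= 3 distinct chain lengths")
        if any(rg <= 0 or n < 2 for n, rg in pairs):
            raise ValueError("need Rg > 0 and N >= 2")
        x = np.log([n for n, _ in pairs])
        y = np.log([rg for _, rg in pairs])
        if fix_prefactor:
            nu = float(np.sum(x * (y - np.log(r0))) / np.sum(x * x))
        else:
            nu = float(np.polyfit(x, y, 1)[0])
    if nu <= 0:
        warnings.warn(f"fitted Flory exponent is non-positive ({nu:.3f})")
    return float(nu)


@dataclass(frozen=True)
class RgDistribution:
    bin_edges: np.ndarray
    density: np.ndarray  # normalized probability density
    mean: float
    variance: float

    def to_frame(self) -> pd.DataFrame:
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return pd.DataFrame({"rg": centers, "density": self.density})


def rg_distribution(ensemble, n_bins: int = 50) -> RgDistribution:
    """Probability density of per-frame Rg plus its sample moments."""
    frames = _frames(ensemble)
    rg = (
        np.asarray(ensemble.rg)
        if hasattr(ensemble, "rg") and len(getattr(ensemble, "rg", []))
        else np.array([radius_of_gyration(f) for f in frames])
    )
    if rg.min() == rg.max():  # degenerate: all frames identical
        edges = np.array([rg[0] - 0.5, rg[0] + 0.5])
        density = np.array([1.0])
    else:
        density, edges = np.histogram(rg, bins=n_bins, density=True)
    return RgDistribution(
        bin_edges=edges,
        density=density,
        mean=float(rg.mean()),
        variance=float(rg.var()),
    )


@dataclass(frozen=True)
class ScatteringCurve:
    q: np.ndarray  # Å^-1
    intensity: np.ndarray
    i0: float
    mean_rg: float

    @property
    def kratky_x(self) -> np.ndarray:
        return self.q * self.mean_rg

    @property
    def kratky_y(self) -> np.ndarray:
        return self.kratky_x**2 * self.intensity / self.i0

    def guinier_rg(self, qrg_max: float = 1.0) -> float:
        """Rg from the Guinier slope of ln I vs q² on the q·Rg < qrg_max range."""
        mask = (self.q * self.mean_rg < qrg_max) & (self.q > 0)
        if mask.sum() < 2:
            raise ValueError("not enough points in the Guinier region")
        slope = np.polyfit(self.q[mask] ** 2, np.log(self.intensity[mask]), 1)[0]
        if slope >= 0:
            raise ValueError("non-negative Guinier slope; curve is not decaying")
        return float(np.sqrt(-3.0 * slope))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "q": self.q,
                "I": self.intensity,
                "kratky_x": self.kratky_x,
                "kratky_y": self.kratky_y,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def debye_scattering(ensemble, q_grid: Sequence[float]) -> ScatteringCurve:
    """Orientation-averaged Debye intensity from bead coordinates.

    I(q) = ⟨Σ_i Σ_j sin(q r_ij)/(q r_ij)⟩ with unit form factors, so
    I(0) = N².  q = 0 is handled by the analytic sinc limit.
    """
    frames = _frames(ensemble)
    q = np.asarray(q_grid, dtype=float)
    if np.any(q < 0):
        raise ValueError("q values must be non-negative")
    n = frames.shape[1]
    intensity = np.zeros_like(q)
    for f in frames:
        r = pdist(f)
        # np.sinc(x) = sin(pi x)/(pi x); handles q r = 0 analytically
        intensity += n + 2.0 * np.sinc(np.outer(q, r) / np.pi).sum(axis=1)
    intensity /= len(frames)
    rg = float(np.mean([radius_of_gyration(f) for f in frames]))
    return ScatteringCurve(q=q, intensity=intensity, i0=float(n * n), mean_rg=rg)


@dataclass(frozen=True)
class ContactMap:
    frequencies: np.ndarray  # (n, n), symmetric, zero on excluded band
    cutoff: float
    exclusion: int

    @property
    def n(self) -> int:
        return int(self.frequencies.shape[0])

    def to_frame(self) -> pd.DataFrame:
        """Tidy (i, j, freq) triplets, 1-based, upper triangle only."""
        i, j = np.triu_indices(self.n, k=self.exclusion + 1)
        return pd.DataFrame(
            {"i": i + 1, "j": j + 1, "freq": self.frequencies[i, j]}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def contact_map(ensemble, cutoff: float = 8.0, exclusion: int = 1) -> ContactMap:
    """Pairwise contact frequency over frames.

    A contact is a bead-centre distance below ``cutoff``; pairs with
    |i-j| <= ``exclusion`` are excluded (adjacent residues are always
    in bonded contact and carry no information).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    frames = _frames(ensemble)
    n = frames.shape[1]
    counts = np.zeros((n, n))
    for f in frames:
        counts += squareform(pdist(f) < cutoff).astype(float)
    freq = counts / len(frames)
    ii, jj = np.indices((n, n))
    freq[np.abs(ii - jj) <= exclusion] = 0.0
    return ContactMap(frequencies=freq, cutoff=cutoff, exclusion=exclusion)


@dataclass(frozen=True)
class CysContactNetwork:
    """Contact frequencies restricted to cysteine pairs."""

    cys_positions: Tuple[int, ...]  # 1-based
    frequencies: Dict[Tuple[int, int], float]  # (pos_i, pos_j) -> freq

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cys_i": i, "cys_j": j, "freq": f}
            for (i, j), f in sorted(self.frequencies.items())
        ]
        return pd.DataFrame(rows, columns=["cys_i", "cys_j", "freq"])


def cys_contact_network(
    ensemble,
    cys_positions: Sequence[int],
    cutoff: float = 8.0,
    exclusion: int = 1,
) -> CysContactNetwork:
    """Contact-frequency network over cysteine pairs.

    Vicinal cysteines (sequence separation <= ``exclusion``) are
    excluded by the adjacency rule, matching the convention that
    contacts between adjacent residues are never registered.
    """
    frames = _frames(ensemble)
    n = frames.shape[1]
    for p in cys_positions:
        if not 1 <= p <= n:
            raise ValueError(f"cysteine position {p} outside chain of length {n}")
    cys = tuple(sorted(cys_positions))
    freqs: Dict[Tuple[int, int], float] = {}
    if len(cys) >= 2:
        cmap = contact_map(ensemble, cutoff=cutoff, exclusion=exclusion)
        for a in range(len(cys)):
            for b in range(a + 1, len(cys)):
                i, j = cys[a], cys[b]
                if j - i <= exclusion:
                    continue
                freqs[(i, j)] = float(cmap.frequencies[i - 1, j - 1])
    return CysContactNetwork(cys_positions=cys, frequencies=freqs)


def summary_json(ensemble, path=None, r0: float = 2.0) -> dict:
    """Per-run summary (mean_Rg, var_Rg, R_shape, nu) as a JSON-able dict."""
    stats = shape_factor(ensemble, r0=r0)
    out = stats.to_dict()
    if hasattr(ensemble, "metadata"):
        out["metadata"] = ensemble.metadata
    if path is not None:
        with open(path, "w") as fh:
            json.dump(out, fh, indent=2, default=float)
    return out
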