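"""Sequence-level statistics for disordered storage proteins.

Windowed hydropathy profiles (ProtScale-style: only full windows are
scored, the value is assigned to the centre residue), the accumulated
hydropathy index, the charge census, and the Das–Pappu diagram-of-states
classification used to place IDPs into conformational classes R1–R5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .scales import ResidueScaleTable
from .sequence_io import ProteinSequence


@dataclass(frozen=True)
class HydropathyProfile:
    """Windowed scale profile over a sequence.

    ``positions`` are 1-based centre indices; only full windows are
    scored, so there are ``len(seq) - window + 1`` of them.  ``mean`` is
    the accumulated hydropathy index (arithmetic mean of the windowed
    values); ``variation`` its population variance, with the sample
    variance and standard deviation also reported.
    """

    scale_name: str
    window: int
    positions: Tuple[int, ...]
    values: Tuple[float, ...]

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def variation(self) -> float:
        return float(np.var(self.values))

    @property
    def sample_variance(self) -> float:
        return float(np.var(self.values, ddof=1)) if len(self.values) > 1 else 0.0

    @property
    def std(self) -> float:
        return float(np.std(self.values))

    def to_frame(self, seq: Optional[ProteinSequence] = None) -> pd.DataFrame:
        df = pd.DataFrame({"position": self.positions, "value": self.values})
        if seq is not None:
            df.insert(1, "residue", [seq.residues[p - 1] for p in self.positions])
        return df

    def to_csv(self, path, seq: Optional[ProteinSequence] = None) -> None:
        self.to_frame(seq).to_csv(path, index=False)


@dataclass(frozen=True)
class ChargeCensus:
    """Counts and fractions of charged residues plus the Das–Pappu label."""

    n_pos: int
    n_neg: int
    length: int

    @property
    def net(self) -> int:
        return self.n_pos - self.n_neg

    @property
    def f_pos(self) -> float:
        return self.n_pos / self.length

    @property
    def f_neg(self) -> float:
        return self.n_neg / self.length

    @property
    def fcr(self) -> float:
        return self.f_pos + self.f_neg

    @property
    def ncpr(self) -> float:
        return self.f_pos - self.f_neg

    @property
    def das_pappu_region(self) -> str:
        return das_pappu_classify(self)

    def to_dict(self) -> dict:
        return {
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "length": self.length,
            "net": self.net,
            "f_pos": self.f_pos,
            "f_neg": self.f_neg,
            "FCR": self.fcr,
            "NCPR": self.ncpr,
            "das_pappu_region": self.das_pappu_region,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def hydropathy_profile(
    seq: ProteinSequence, table: ResidueScaleTable, window: int = 15
) -> HydropathyProfile:
    """Sliding-window mean of a residue scale over a sequence.

    Each value is the unweighted mean of the table values over the
    window centred at that position.  The window must be odd and no
    longer than the sequence.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if not 1 <= window <= len(seq):
        raise ValueError(
            f"window {window} out of range for sequence of length {len(seq)}"
        )
    raw = np.array([table[c] for c in seq.residues], dtype=float)
    kernel = np.ones(window) / window
    values = np.convolve(raw, kernel, mode="valid")
    half = window // 2
    positions = tuple(range(half + 1, len(seq) - half + 1))
    return HydropathyProfile(
        scale_name=table.name,
        window=window,
        positions=positions,
        values=tuple(float(v) for v in values),
    )


def charge_census(seq: ProteinSequence, scheme: ResidueScaleTable) -> ChargeCensus:
    if scheme.name != "charge_scheme":
        raise ValueError("charge_census requires a charge_scheme table")
    charges = [int(scheme[c]) for c in seq.residues]
    n_pos = sum(1 for z in charges if z > 0)
    n_neg = sum(1 for z in charges if z < 0)
    if getattr(scheme, "charged_termini", False):
        n_pos += 1  # N-terminal amine
        n_neg += 1  # C-terminal carboxylate
    return ChargeCensus(n_pos=n_pos, n_neg=n_neg, length=len(seq))


def das_pappu_classify(census: ChargeCensus) -> str:
    """Diagram-of-states region from charge fractions.

    R1 weak polyampholytes/polyelectrolytes (globule or tadpole); R2 the
    boundary Janus region; R3 strong polyampholytes (coils/hairpins); R4
    and R5 strong positive/negative polyelectrolytes.  Ties on the
    boundaries resolve to the lower-numbered region.
    """
    fp, fn, fcr = census.f_pos, census.f_neg, census.fcr
    if fcr < 0.25:
        return "R1"
    if fcr <= 0.35:
        return "R2"
    if fp > 0.35 and fn <= 0.35:
        return "R4"
    if fn > 0.35 and fp <= 0.35:
        return "R5"
    return "R3"


@dataclass(frozen=True)
class CysContext:
    """Windowed hydropathy at one cysteine position."""

    position: int
    value: float
    hydrophobic: bool
    truncated: bool  # True if the nearest full-window position was used


def cys_context(
    seq: ProteinSequence,
    profile: HydropathyProfile,
    threshold: float = 0.0,
) -> List[CysContext]:
    """Sequence context of each cysteine.

    Returns the windowed hydropathy value at (or, in window-truncated
    terminal regions, nearest to) each cysteine position, classified
    hydrophobic if the value exceeds ``threshold``.
    """
    first, last = profile.positions[0], profile.positions[-1]
    out = []
    for pos in seq.cys_positions:
        clamped = min(max(pos, first), last)
        value = profile.values[clamped - first]
        out.append(
            CysContext(
                position=pos,
                value=float(value),
                hydrophobic=value > threshold,
                truncated=clamped != pos,
            )
        )
    return out
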