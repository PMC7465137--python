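"""Per-residue property scales.

Three scales are shipped: the Kyte–Doolittle hydropathy scale, the Rose
et al. mean-buried-area scale, and a configurable integer charge scheme.
All are exposed as :class:`ResidueScaleTable` objects mapping the 20
standard one-letter codes to real numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# Kyte & Doolittle (1982) hydropathy values.
KYTE_DOOLITTLE_VALUES: Mapping[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Rose et al. (1985) mean fractional area loss on folding (buriedness).
ROSE_VALUES: Mapping[str, float] = {
    "A": 0.74, "R": 0.64, "N": 0.63, "D": 0.62, "C": 0.91,
    "Q": 0.62, "E": 0.62, "G": 0.72, "H": 0.78, "I": 0.88,
    "L": 0.85, "K": 0.52, "M": 0.85, "F": 0.88, "P": 0.64,
    "S": 0.66, "T": 0.70, "W": 0.85, "Y": 0.76, "V": 0.86,
}


@dataclass(frozen=True)
class ResidueScaleTable:
    """A total map from the 20 standard residue codes to real values."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(STANDARD_AA) - set(self.values)
        extra = set(self.values) - set(STANDARD_AA)
        if missing or extra:
            raise ValueError(
                f"scale {self.name!r} must cover exactly the 20 standard "
                f"residues (missing={sorted(missing)}, extra={sorted(extra)})"
            )
        if self.name == "charge_scheme" and any(
            v not in (-1, 0, 1) for v in self.values.values()
        ):
            raise ValueError("charge_scheme values must be in {-1, 0, +1}")

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise KeyError(f"unknown residue code {residue!r}") from None


def scale_lookup(table: ResidueScaleTable, residue: str) -> float:
    """Look up one residue in a scale table; total over the 20 codes."""
    return table[residue]


def kyte_doolittle() -> ResidueScaleTable:
    return ResidueScaleTable("kyte_doolittle", dict(KYTE_DOOLITTLE_VALUES))


def rose() -> ResidueScaleTable:
    return ResidueScaleTable("rose", dict(ROSE_VALUES))


def charge_scheme(
    his_positive: bool = False,
    charged_termini: bool = False,
) -> ResidueScaleTable:
    """Integer charge per residue at physiological pH.

    Default: Arg and Lys +1; Asp and Glu -1; His and the termini neutral.
    ``charged_termini`` is carried as table metadata and honoured by the
    charge census (N-terminus +1, C-terminus -1); it does not alter the
    per-residue values.
    """
    values = {aa: 0 for aa in STANDARD_AA}
    values["R"] = values["K"] = 1
    values["D"] = values["E"] = -1
    if his_positive:
        values["H"] = 1
    table = ResidueScaleTable("charge_scheme", values)
    # frozen dataclass: stash the termini flag via object.__setattr__
    object.__setattr__(table, "charged_termini", charged_termini)
    return table
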