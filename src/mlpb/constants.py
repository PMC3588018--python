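"""Physical constants (CODATA 2018) in SI units.

Single source of truth for the whole package: every module that needs the
elementary charge, the Boltzmann constant, etc. imports :data:`CONSTANTS`
from here.  Unit conversions to/from user-facing units (Debye, mol/l, nm,
mV) live at the I/O boundary only; internally everything is SI.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass(frozen=True)
class PhysicalConstants:
    """Frozen CODATA values used by the electrostatic model.

    Attributes
    ----------
    e0 : elementary charge (C)
    eps0 : vacuum permittivity (F/m)
    kB : Boltzmann constant (J/K)
    NA : Avogadro constant (1/mol)
    debye : one Debye in C*m (dipole-moment unit conversion)
    """

    e0: float = 1.602176634e-19
    eps0: float = 8.8541878128e-12
    kB: float = 1.380649e-23
    NA: float = 6.02214076e23
    debye: float = 3.33564e-30

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0.0:
                raise ValueError(f"constant {f.name} must be strictly positive")


#: The package-wide constant set.
CONSTANTS = PhysicalConstants()

#: Conversion factor mol/l -> number density 1/m^3.
MOL_PER_L_TO_PER_M3 = CONSTANTS.NA * 1.0e3

#: Conversion factor nm -> m.
NM = 1.0e-9
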