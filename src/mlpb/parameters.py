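"""Model parameters for the planar zwitterionic headgroup layer.

The model describes a planar lipid layer whose dipolar (zwitterionic)
headgroups carry a negative charge smeared on the plane ``x = 0`` (surface
charge density ``sigma = -e0/a0``) and a positive charge Boltzmann-distributed
over ``0 < x <= D``, in contact with a monovalent salt solution whose water
permittivity saturates in strong fields.

All :class:`ModelParameters` fields are SI; use
:meth:`ModelParameters.from_user_units` or the DPPC presets to construct
instances from laboratory units (K, nm^2, nm, Debye, mol/l).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .constants import CONSTANTS, MOL_PER_L_TO_PER_M3, NM

#: DPPC gel <-> liquid-crystalline main transition temperature (K).
TRANSITION_TEMPERATURE_K = 314.0

#: Area per DPPC lipid in the gel phase (m^2), T below the transition.
AREA_GEL_M2 = 0.48 * NM**2

#: Area per DPPC lipid in the liquid-crystalline phase (m^2), T above it.
AREA_LIQUID_M2 = 0.60 * NM**2


@dataclass(frozen=True)
class ModelParameters:
    """Physical inputs of the modified Langevin-Poisson-Boltzmann model (SI).

    Attributes
    ----------
    T : temperature (K)
    a0 : area per lipid (m^2); sets the surface charge density -e0/a0
    D : headgroup charge separation, P-N distance (m)
    p0 : water dipole moment magnitude (C*m)
    n0 : bulk salt number density (1/m^3)
    n0w : bulk water number density (1/m^3)
    n_refr : optical refractive index of water (dimensionless)
    alpha : optional lattice-statistics volume-ratio parameter; ``None``
        selects the point-like Boltzmann headgroup distribution, a positive
        value the finite-volume (lattice) form
    L : domain length (m); far boundary where the field is taken to vanish
    """

    T: float
    a0: float
    D: float
    p0: float
    n0: float
    n0w: float
    n_refr: float = 1.33
    alpha: float | None = None
    L: float = 12.0 * NM

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature T must be positive")
        if self.a0 <= 0:
            raise ValueError("area per lipid a0 must be positive")
        if not (0 < self.D < self.L):
            raise ValueError("charge separation D must satisfy 0 < D < L")
        if self.p0 <= 0:
            raise ValueError("water dipole moment p0 must be positive")
        if self.n0 < 0:
            raise ValueError("bulk salt density n0 must be non-negative")
        if self.n0w <= 0:
            raise ValueError("bulk water density n0w must be positive")
        if self.n_refr < 1:
            raise ValueError("refractive index must be >= 1")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("lattice parameter alpha must be positive when set")

    # -- derived quantities -------------------------------------------------

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/kT (1/J)."""
        return 1.0 / (CONSTANTS.kB * self.T)

    @property
    def sigma(self) -> float:
        """Surface charge density -e0/a0 at the x = 0 plane (C/m^2)."""
        return -CONSTANTS.e0 / self.a0

    @property
    def n_squared(self) -> float:
        """Square of the optical refractive index (electronic permittivity)."""
        return self.n_refr**2

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_user_units(
        cls,
        *,
        T: float = 310.0,
        a0_nm2: float = 0.48,
        d_nm: float = 0.42,
        p0_debye: float = 3.1,
        salt_mol_l: float = 0.1,
        water_mol_l: float = 55.0,
        n_refr: float = 1.33,
        alpha: float | None = None,
        l_nm: float = 12.0,
    ) -> "ModelParameters":
        """Build parameters from laboratory units (K, nm^2, nm, Debye, mol/l)."""
        return cls(
            T=T,
            a0=a0_nm2 * NM**2,
            D=d_nm * NM,
            p0=p0_debye * CONSTANTS.debye,
            n0=salt_mol_l * MOL_PER_L_TO_PER_M3,
            n0w=water_mol_l * MOL_PER_L_TO_PER_M3,
            n_refr=n_refr,
            alpha=alpha,
            L=l_nm * NM,
        )

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given SI fields replaced."""
        return dataclasses.replace(self, **changes)


def area_per_lipid(T: float) -> float:
    """Area per DPPC lipid (m^2) selected by the phase rule.

    Below the main transition (314 K) the chains are in the ordered gel
    phase (0.48 nm^2 per lipid); above it, in the liquid-crystalline phase
    (0.60 nm^2).  The transition temperature itself is excluded: the model
    contains no description of the transition, so no area is defined there.
    """
    if T == TRANSITION_TEMPERATURE_K:
        raise ValueError(
            f"T = {TRANSITION_TEMPERATURE_K:g} K is the gel/liquid transition "
            "temperature; the model is undefined in the transition gap"
        )
    return AREA_GEL_M2 if T < TRANSITION_TEMPERATURE_K else AREA_LIQUID_M2


def dppc_gel(T: float = 310.0) -> ModelParameters:
    """DPPC preset in the gel phase (default T = 310 K, a0 = 0.48 nm^2)."""
    if T >= TRANSITION_TEMPERATURE_K:
        raise ValueError("gel preset requires T below the 314 K transition")
    return ModelParameters.from_user_units(T=T, a0_nm2=0.48)


def dppc_liquid(T: float = 323.0) -> ModelParameters:
    """DPPC preset in the liquid-crystalline phase (default T = 323 K)."""
    if T <= TRANSITION_TEMPERATURE_K:
        raise ValueError("liquid preset requires T above the 314 K transition")
    return ModelParameters.from_user_units(T=T, a0_nm2=0.60)
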