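"""Pointwise physics of the modified Langevin-Poisson-Boltzmann model.

Closed-form building blocks, all vectorised over numpy arrays:

* the Langevin function and the field-dependent water permittivity with its
  zero-field (Onsager) limit,
* Boltzmann ion densities and the ionic charge density of a monovalent
  symmetric electrolyte,
* the headgroup positive-charge probability density on ``[0, D]`` — the
  point-like Boltzmann form and the finite-volume lattice-statistics form —
  and the volume charge density it induces.

Everything here is a pure function of a potential/field value and a
:class:`~mlpb.parameters.ModelParameters` instance; the self-consistent
coupling happens in :mod:`mlpb.solver`.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .constants import CONSTANTS
from .parameters import ModelParameters

__all__ = [
    "langevin",
    "langevin_over_u",
    "gamma_factor",
    "polarization",
    "relative_permittivity",
    "onsager_permittivity",
    "ion_number_densities",
    "ion_charge_density",
    "headgroup_probability",
    "headgroup_charge_density",
]

# coth(u) - 1/u cancels catastrophically near u = 0 (relative error ~eps/u^2);
# below this threshold the Taylor series u/3 - u^3/45 + 2u^5/945 is the more
# accurate branch: at the switch point both branches agree to ~1e-11 relative
# (series truncation ~u^6/4725, closed-form roundoff ~eps/u^2).
_SERIES_THRESHOLD = 1e-2

# |e0 phi beta| beyond this overflows exp(); it can only arise from a
# diverged outer iteration, never from a physical potential (~700 kT).
_BOLTZMANN_OVERFLOW = 700.0


def langevin(u: ArrayLike) -> NDArray[np.float64] | float:
    """Langevin function L(u) = coth(u) - 1/u.

    Mean alignment of a classical dipole of energy ``-p E cos(theta)`` in a
    thermal bath; odd, strictly increasing, saturating at +/-1.  Small
    arguments use the Taylor series ``u/3 - u^3/45 + 2 u^5/945`` so that
    ``langevin(0.0) == 0.0`` exactly.
    """
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < _SERIES_THRESHOLD
    # avoid 1/0 warnings in the masked branch
    safe = np.where(small, 1.0, u)
    closed = 1.0 / np.tanh(safe) - 1.0 / safe
    u2 = u * u
    series = u * (1.0 / 3.0 - u2 / 45.0 + 2.0 * u2 * u2 / 945.0)
    out = np.where(small, series, closed)
    return float(out) if out.ndim == 0 else out


def langevin_over_u(u: ArrayLike) -> NDArray[np.float64] | float:
    """L(u)/u, continuously extended to its limit 1/3 at u = 0.

    Even, strictly decreasing in |u|, with range (0, 1/3].  This ratio is
    the shape factor of the field-dependent permittivity.
    """
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < _SERIES_THRESHOLD
    safe = np.where(small, 1.0, u)
    closed = (1.0 / np.tanh(safe) - 1.0 / safe) / safe
    u2 = u * u
    series = 1.0 / 3.0 - u2 / 45.0 + 2.0 * u2 * u2 / 945.0
    out = np.where(small, series, closed)
    return float(out) if out.ndim == 0 else out


def gamma_factor(n_refr: float) -> float:
    """Cavity-field enhancement gamma = (3/2) * (2 + n^2)/3.

    Local-field correction for a point dipole at the centre of a sphere of
    electronic permittivity ``n^2`` embedded in the solution.
    """
    return 1.5 * (2.0 + n_refr**2) / 3.0


def polarization(E: ArrayLike, params: ModelParameters) -> NDArray[np.float64] | float:
    """Water orientational polarization magnitude P(E) in C/m^2.

    ``P = n0w * ((2+n^2)/3) * p0 * L(gamma p0 E beta)`` — monotonically
    increasing in the field magnitude ``E >= 0`` and saturating at
    ``n0w ((2+n^2)/3) p0`` once every dipole is aligned.
    """
    cavity = (2.0 + params.n_squared) / 3.0
    u = gamma_factor(params.n_refr) * params.p0 * np.asarray(E, dtype=float) * params.beta
    out = params.n0w * cavity * params.p0 * langevin(u)
    return float(out) if np.ndim(out) == 0 else out


def relative_permittivity(
    E: ArrayLike, params: ModelParameters
) -> NDArray[np.float64] | float:
    """Field-dependent relative permittivity eps_r(E) of the solution.

    ``eps_r = n^2 + (3/2) ((2+n^2)/3)^2 (n0w p0^2 beta / eps0) * L(u)/u``
    with ``u = gamma p0 E beta``.  Strictly decreasing in the field
    magnitude: at ``E = 0`` it equals the Onsager (bulk) value, and as
    ``E -> inf`` the orientational term dies out leaving the electronic
    contribution ``n^2`` (dielectric saturation).
    """
    cavity = (2.0 + params.n_squared) / 3.0
    coeff = 1.5 * cavity**2 * params.n0w * params.p0**2 * params.beta / CONSTANTS.eps0
    u = gamma_factor(params.n_refr) * params.p0 * np.asarray(E, dtype=float) * params.beta
    out = params.n_squared + coeff * langevin_over_u(u)
    return float(out) if np.ndim(out) == 0 else out


def onsager_permittivity(params: ModelParameters) -> float:
    """Zero-field (Onsager) bulk permittivity.

    Closed form ``n^2 + ((2+n^2)/3)^2 n0w p0^2 beta / (2 eps0)``; evaluated
    as ``relative_permittivity(E=0)`` so the two are identical by
    construction.  With p0 = 3.1 Debye, 55 mol/l water and n = 1.33 this
    gives 78.5 at 298 K.
    """
    return float(relative_permittivity(0.0, params))


def ion_number_densities(
    phi: ArrayLike, params: ModelParameters
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Boltzmann number densities (n_plus, n_minus) of the monovalent ions.

    ``n± = n0 exp(∓ e0 phi beta)`` — counter-ions accumulate where the
    potential is negative, co-ions deplete.  The product ``n+ n- = n0^2``
    identically (ideal-solution mass action).

    Raises
    ------
    OverflowError
        if ``|e0 phi beta| > 700``, which can only mean a diverged solver
        state upstream.
    """
    phi = np.asarray(phi, dtype=float)
    if not np.all(np.isfinite(phi)):
        raise ValueError("potential contains non-finite values")
    u = CONSTANTS.e0 * phi * params.beta
    if np.any(np.abs(u) > _BOLTZMANN_OVERFLOW):
        raise OverflowError(
            "Boltzmann exponent |e0*phi*beta| exceeds 700: the potential is "
            "unphysically large, indicating a diverged solver state"
        )
    return params.n0 * np.exp(-u), params.n0 * np.exp(u)


def ion_charge_density(
    phi: ArrayLike, params: ModelParameters
) -> NDArray[np.float64] | float:
    """Net ionic charge density rho_ions = -2 e0 n0 sinh(e0 phi beta) in C/m^3.

    Odd in phi and of opposite sign (screening): a negative potential draws
    a positive counter-ion excess.
    """
    phi = np.asarray(phi, dtype=float)
    u = CONSTANTS.e0 * phi * params.beta
    if np.any(np.abs(u) > _BOLTZMANN_OVERFLOW):
        raise OverflowError(
            "Boltzmann exponent |e0*phi*beta| exceeds 700: diverged solver state"
        )
    out = -2.0 * CONSTANTS.e0 * params.n0 * np.sinh(u)
    return float(out) if out.ndim == 0 else out


def headgroup_probability(
    x: ArrayLike,
    phi: ArrayLike,
    params: ModelParameters,
    alpha: float | None = None,
) -> tuple[NDArray[np.float64], float]:
    """Probability density p(x) of the headgroup positive charge on [0, D].

    The point-like (Boltzmann) form is ``p = Lambda exp(-e0 phi beta)``;
    with a finite headgroup volume ratio ``alpha`` the lattice-statistics
    form ``p = Lambda alpha w / (alpha w + 1)``, ``w = exp(-e0 phi beta)``,
    saturates instead of growing exponentially.  Either way Lambda is fixed
    by the normalization ``(1/D) \\int_0^D p dx = 1`` (trapezoidal
    quadrature on the supplied grid).

    Parameters
    ----------
    x, phi : aligned arrays covering the full interval [0, D]
    alpha : overrides ``params.alpha``; ``None`` falls back to it, and a
        fully absent alpha selects the Boltzmann form.

    Returns
    -------
    (prob, lam) : the density evaluated at ``x`` and the normalization
        constant Lambda.
    """
    x = np.asarray(x, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if x.shape != phi.shape:
        raise ValueError("x and phi must be aligned arrays")
    if not np.all(np.isfinite(phi)):
        raise ValueError("potential contains non-finite values")
    D = x[-1] - x[0]
    if D <= 0:
        raise ValueError("x must span a positive interval")
    if alpha is None:
        alpha = params.alpha
    u = CONSTANTS.e0 * phi * params.beta
    w = np.exp(-u)
    if alpha is None:
        unnorm = w
    else:
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        aw = alpha * w
        unnorm = aw / (aw + 1.0)
    lam = D / np.trapezoid(unnorm, x)
    return lam * unnorm, float(lam)


def headgroup_charge_density(
    prob: ArrayLike,
    x: ArrayLike,
    params: ModelParameters,
) -> NDArray[np.float64] | float:
    """Headgroup positive volume charge density rho_Zw(x) in C/m^3.

    ``rho_Zw = e0 p(x) / (D a0)`` inside the headgroup region and exactly 0
    beyond ``x = D``; the x = 0 endpoint carries the continuous limit of the
    density.  The normalization of p guarantees that rho_Zw integrates to
    ``e0/a0 = -sigma`` over [0, D]: the layer is electrically neutral as a
    whole.

    ``prob`` must hold the density at every ``x <= D`` (values beyond D are
    ignored); a scalar prob is broadcast.
    """
    x = np.asarray(x, dtype=float)
    prob = np.broadcast_to(np.asarray(prob, dtype=float), x.shape)
    inside = x <= params.D
    out = np.where(inside, CONSTANTS.e0 * prob / (params.D * params.a0), 0.0)
    return float(out) if out.ndim == 0 else out
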