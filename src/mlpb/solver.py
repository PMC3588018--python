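"""Self-consistent solution of the modified Langevin-Poisson-Boltzmann BVP.

The governing equation on ``[0, L]`` is the variable-coefficient Poisson
equation

    d/dx [ eps0 eps_r(|phi'|) phi' ] = 2 e0 n0 sinh(e0 phi beta) - rho_Zw(x)

with a prescribed-flux boundary at the charged plane,
``eps0 eps_r(0) phi'(0) = -sigma``, and a zero-field (Neumann) boundary at
the far end ``x = L``.  The bulk reference ``phi -> 0`` is not imposed: the
sinh term pins the solution to it because the ion densities are written with
bulk prefactors, so the Neumann pair is well-posed.

Discretization is a conservative finite-volume scheme: fluxes
``eps0 eps_r phi'`` live on cell faces with ``eps_r`` evaluated at the face
field of the previous iterate, which makes potential and flux continuity at
the headgroup boundary ``x = D`` automatic.  The nonlinearity is handled by
a damped Picard outer loop in which the ionic sinh and the headgroup
Boltzmann factor are Newton-linearized about the current iterate while
``eps_r`` and the headgroup normalization Lambda are lagged; both Jacobian
contributions are positive, so every inner tridiagonal system is a strictly
diagonally dominant M-matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy.linalg import solve_banded

from .constants import CONSTANTS
from .core import ion_charge_density, relative_permittivity
from .grid import Grid, build_grid
from .parameters import ModelParameters

__all__ = [
    "SolverOptions",
    "SolutionState",
    "ConvergenceError",
    "solve_mlpb",
    "gouy_chapman_reference",
    "debye_length",
    "residual_diagnostics",
]


class ConvergenceError(RuntimeError):
    """Outer iteration failed to converge; carries the residual history."""

    def __init__(self, message: str, residual_history: list[float]):
        super().__init__(message)
        self.residual_history = residual_history


@dataclass(frozen=True)
class SolverOptions:
    """Knobs of the damped Picard outer iteration.

    Attributes
    ----------
    max_outer_iterations : hard cap on outer sweeps
    damping : relaxation factor in (0, 1] applied to each update
    tolerance : convergence threshold on the max nodewise potential update
        of a full (undamped) sweep, in volts
    initial_guess : only ``"zero"`` is defined — phi = 0, eps_r = Onsager,
        Lambda = 1, which lies in the attraction basin for all physical
        parameter sets
    include_headgroups : include the headgroup volume charge source
    include_surface_charge : include sigma in the x = 0 flux boundary
        (disabling both reduces the problem to an uncharged half-space)
    fixed_permittivity : if set, freeze eps_r at this constant instead of
        the field-dependent law (used for validation against the classical
        constant-permittivity double layer)
    """

    max_outer_iterations: int = 10_000
    damping: float = 0.25
    tolerance: float = 1e-9
    initial_guess: str = "zero"
    include_headgroups: bool = True
    include_surface_charge: bool = True
    fixed_permittivity: float | None = None

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if not (0 < self.damping <= 1):
            raise ValueError("damping must lie in (0, 1]")
        if self.max_outer_iterations < 1:
            raise ValueError("max_outer_iterations must be >= 1")
        if self.initial_guess != "zero":
            raise ValueError("only the 'zero' initial guess policy is defined")
        if self.fixed_permittivity is not None and self.fixed_permittivity <= 0:
            raise ValueError("fixed_permittivity must be positive")


@dataclass(frozen=True)
class SolutionState:
    """Converged (or final) state of the boundary-value problem.

    Attributes
    ----------
    grid : the spatial grid
    phi : potential at the nodes (V)
    efield : field magnitude |phi'| at the nodes (V/m), centred differences
        inside, one-sided at the boundaries
    eps_r : relative permittivity at the nodes evaluated at ``efield``
    lambda_norm : headgroup normalization constant Lambda
    converged : whether the tolerance was met
    iterations : outer sweeps performed
    final_residual : last max nodewise |delta phi| (V)
    residual_history : residual after each sweep
    """

    grid: Grid
    phi: NDArray[np.float64]
    efield: NDArray[np.float64]
    eps_r: NDArray[np.float64]
    lambda_norm: float
    converged: bool
    iterations: int
    final_residual: float
    residual_history: list[float] = field(repr=False, default_factory=list)


def _face_field(phi: NDArray, h: NDArray) -> NDArray:
    """|phi'| on the cell faces."""
    return np.abs(np.diff(phi)) / h


def _node_field(phi: NDArray, x: NDArray) -> NDArray:
    """|phi'| on the nodes: centred differences, one-sided at the ends."""
    E = np.empty_like(phi)
    E[1:-1] = (phi[2:] - phi[:-2]) / (x[2:] - x[:-2])
    E[0] = (phi[1] - phi[0]) / (x[1] - x[0])
    E[-1] = (phi[-1] - phi[-2]) / (x[-1] - x[-2])
    return np.abs(E)


def solve_mlpb(
    params: ModelParameters,
    grid: Grid | None = None,
    opts: SolverOptions | None = None,
) -> SolutionState:
    """Solve the headgroup-layer boundary-value problem self-consistently.

    Each outer sweep (i) evaluates eps_r on the cell faces at the current
    face fields, (ii) recomputes the headgroup normalization Lambda from the
    current potential, (iii) assembles and solves the Newton-linearized
    tridiagonal system, and (iv) relaxes the update by ``opts.damping``.
    Convergence is declared when the undamped update falls below
    ``opts.tolerance`` everywhere.

    Raises
    ------
    ConvergenceError
        if the iteration cap is reached or a Boltzmann factor overflows
        (the latter suggests a smaller damping factor).
    """
    opts = opts or SolverOptions()
    grid = grid or build_grid(params)
    x = grid.x
    n = x.size
    h = np.diff(x)                      # face spacings
    vol = np.empty(n)                   # control-volume widths
    vol[1:-1] = 0.5 * (h[:-1] + h[1:])
    vol[0] = 0.5 * h[0]
    vol[-1] = 0.5 * h[-1]

    e0, eps0 = CONSTANTS.e0, CONSTANTS.eps0
    beta = params.beta
    sigma = params.sigma if opts.include_surface_charge else 0.0
    d_idx = grid.d_index
    in_head = np.zeros(n)
    in_head[: d_idx + 1] = 1.0          # closed interval [0, D]
    # the headgroup source ends exactly at x = D, so the node there only
    # collects it over the half-cell inside [0, D]
    vol_head = vol * in_head
    vol_head[d_idx] = 0.5 * h[d_idx - 1]

    phi = np.zeros(n)
    lam = 1.0
    residual_history: list[float] = []
    converged = False
    iterations = 0

    ab = np.zeros((3, n))               # banded matrix (upper, diag, lower)
    for iterations in range(1, opts.max_outer_iterations + 1):
        u = e0 * phi * beta
        if np.any(np.abs(u) > 700.0):
            raise ConvergenceError(
                "Boltzmann factor overflow: the iteration diverged; "
                "try a smaller damping factor",
                residual_history,
            )
        # face permittivities at the lagged field
        if opts.fixed_permittivity is not None:
            eps_face = np.full(n - 1, opts.fixed_permittivity)
        else:
            eps_face = relative_permittivity(_face_field(phi, h), params)
        K = eps0 * eps_face / h         # face conductances

        # sources, Newton-linearized about the current iterate:
        #   ionic term q_i = 2 e0 n0 sinh(u),       dq/dphi = 2 e0^2 n0 beta cosh(u)
        #   headgroup  q_h = -e0 lam exp(-u)/(D a0), dq/dphi = +e0^2 beta lam exp(-u)/(D a0)
        w = np.exp(-u)
        if opts.include_headgroups:
            lam = params.D / np.trapezoid(w[: d_idx + 1], x[: d_idx + 1])
            head_coeff = e0 * lam / (params.D * params.a0) * in_head
        else:
            lam = 1.0
            head_coeff = np.zeros(n)
        q_ion = 2.0 * e0 * params.n0 * np.sinh(u)
        jac_ion = 2.0 * e0**2 * params.n0 * beta * np.cosh(u)
        q_head = -head_coeff * w
        jac_head = e0 * beta * head_coeff * w

        # assemble:  K_{i-1/2} phi_{i-1} - (K_{i-1/2}+K_{i+1/2}+V_i J_i) phi_i
        #            + K_{i+1/2} phi_{i+1} = V_i (q_i - J_i phi_i) [+ boundary terms]
        rhs = vol * (q_ion - jac_ion * phi) + vol_head * (q_head - jac_head * phi)
        ab[0, 1:] = K                   # superdiagonal (phi_{i+1})
        ab[2, :-1] = K                  # subdiagonal (phi_{i-1})
        ab[1, :] = -(vol * jac_ion + vol_head * jac_head)
        ab[1, :-1] -= K
        ab[1, 1:] -= K
        rhs[0] -= sigma                 # incoming flux eps0 eps_r phi'(0) = -sigma
        # (far boundary: zero flux, nothing to add)
        ab[0, 0] = 0.0
        ab[2, -1] = 0.0

        phi_new = solve_banded((1, 1), ab, rhs)
        residual = float(np.max(np.abs(phi_new - phi)))
        residual_history.append(residual)
        phi = phi + opts.damping * (phi_new - phi)
        if residual < opts.tolerance:
            phi = phi_new               # accept the converged sweep in full
            converged = True
            break

    if not converged:
        raise ConvergenceError(
            f"no convergence after {iterations} sweeps "
            f"(last residual {residual_history[-1]:.3e} V)",
            residual_history,
        )

    if opts.include_headgroups:
        w = np.exp(-e0 * phi * beta)
        lam = params.D / np.trapezoid(w[: d_idx + 1], x[: d_idx + 1])

    efield = _node_field(phi, x)
    if opts.fixed_permittivity is not None:
        eps_nodes = np.full(n, opts.fixed_permittivity)
    else:
        eps_nodes = np.asarray(relative_permittivity(efield, params))
    return SolutionState(
        grid=grid,
        phi=phi,
        efield=efield,
        eps_r=eps_nodes,
        lambda_norm=float(lam),
        converged=True,
        iterations=iterations,
        final_residual=residual_history[-1],
        residual_history=residual_history,
    )


def debye_length(params: ModelParameters, eps_const: float) -> float:
    """Debye screening length sqrt(eps eps0 kT / (2 n0 e0^2)) in metres."""
    return float(
        np.sqrt(
            eps_const
            * CONSTANTS.eps0
            / (2.0 * params.n0 * CONSTANTS.e0**2 * params.beta)
        )
    )


def gouy_chapman_reference(
    params: ModelParameters,
    eps_const: float,
    x: NDArray[np.float64] | None = None,
) -> NDArray[np.float64]:
    """Closed-form constant-permittivity double-layer potential (test oracle).

    The classical diffuse-layer solution for a plane of charge sigma in a
    symmetric monovalent electrolyte of fixed permittivity ``eps_const``:

        phi(x) = (2 kT / e0) ln[(1 + g exp(-kappa x)) / (1 - g exp(-kappa x))]

    with ``kappa`` the inverse Debye length, surface potential from the
    Grahame equation ``sigma = sqrt(8 n0 eps eps0 kT) sinh(e0 phi0 beta / 2)``
    and ``g = tanh(e0 phi0 beta / 4)``.  Headgroups are outside this model;
    it exists purely to validate the numerical solver.
    """
    if eps_const <= 0:
        raise ValueError("eps_const must be positive")
    if x is None:
        x = build_grid(params).x
    sigma = params.sigma
    if sigma == 0.0 or params.n0 == 0.0:
        return np.zeros_like(x)
    e0, eps0 = CONSTANTS.e0, CONSTANTS.eps0
    beta = params.beta
    kT = 1.0 / beta
    phi0 = (2.0 / (e0 * beta)) * np.arcsinh(
        sigma / np.sqrt(8.0 * params.n0 * eps_const * eps0 * kT)
    )
    g = np.tanh(e0 * phi0 * beta / 4.0)
    kappa = 1.0 / debye_length(params, eps_const)
    ge = g * np.exp(-kappa * np.asarray(x, dtype=float))
    return (2.0 * kT / e0) * np.log((1.0 + ge) / (1.0 - ge))


def residual_diagnostics(state: SolutionState, params: ModelParameters) -> dict:
    """A posteriori checks of a solution against the continuous problem.

    Returns a dict with:

    * ``max_residual`` — max pointwise defect of the discretized equation
      (V, same scale as the solver tolerance normalised by conductance);
    * ``flux_jump_at_D`` — mismatch of eps0 eps_r phi' across the headgroup
      boundary (C/m^2);
    * ``bc_mismatch_surface`` — |eps0 eps_r(0) phi'(0) + sigma| (C/m^2);
    * ``bc_mismatch_far`` — |phi'(L)| (V/m) and ``phi_far`` = phi(L) (V);
    * ``charge_balance`` — relative electroneutrality defect
      |sigma + integral(rho_Zw + rho_ions)| / |sigma| (absolute if sigma=0).

    Never raises on a bad state: a perturbed potential simply reports large
    residuals.
    """
    x = state.grid.x
    phi = state.phi
    h = np.diff(x)
    eps_face = _diagnostic_face_eps(state, params, h)
    flux = CONSTANTS.eps0 * eps_face * np.diff(phi) / h

    d_idx = state.grid.d_index
    e0 = CONSTANTS.e0
    u = e0 * phi * params.beta
    w = np.exp(-np.clip(u, -700, 700))
    lam = params.D / np.trapezoid(w[: d_idx + 1], x[: d_idx + 1])
    rho_zw = np.zeros_like(phi)
    rho_zw[: d_idx + 1] = e0 * lam * w[: d_idx + 1] / (params.D * params.a0)
    rho_ions = np.asarray(ion_charge_density(np.clip(phi, -1.0, 1.0), params))

    vol = np.empty_like(phi)
    vol[1:-1] = 0.5 * (h[:-1] + h[1:])
    vol[0], vol[-1] = 0.5 * h[0], 0.5 * h[-1]
    vol_head = np.zeros_like(vol)
    vol_head[:d_idx] = vol[:d_idx]
    vol_head[d_idx] = 0.5 * h[d_idx - 1]  # headgroup support ends at D
    weighted = -vol * rho_ions - vol_head * rho_zw
    defect = np.empty_like(phi)
    defect[1:-1] = (flux[1:] - flux[:-1]) - weighted[1:-1]
    defect[0] = flux[0] + params.sigma - weighted[0]
    defect[-1] = -flux[-1] - weighted[-1]
    # express the defect as an equivalent potential perturbation
    K_scale = np.median(CONSTANTS.eps0 * eps_face / h)
    max_residual = float(np.max(np.abs(defect)) / K_scale)

    charge = float(
        params.sigma
        + np.trapezoid(rho_zw[: d_idx + 1], x[: d_idx + 1])
        + np.trapezoid(rho_ions, x)
    )
    denom = abs(params.sigma) if params.sigma != 0.0 else 1.0
    return {
        "max_residual": max_residual,
        "flux_jump_at_D": float(abs(flux[d_idx] - flux[d_idx - 1])) if d_idx >= 1 else 0.0,
        "bc_mismatch_surface": float(
            abs(CONSTANTS.eps0 * state.eps_r[0] * (phi[1] - phi[0]) / h[0] + params.sigma)
        ),
        "bc_mismatch_far": float(abs(phi[-1] - phi[-2]) / h[-1]),
        "phi_far": float(phi[-1]),
        "charge_balance": abs(charge) / denom,
    }


def _diagnostic_face_eps(
    state: SolutionState, params: ModelParameters, h: NDArray
) -> NDArray:
    """Face permittivities consistent with how the state was produced."""
    eps_flat = np.unique(state.eps_r)
    if eps_flat.size == 1:
        # frozen-permittivity solve
        return np.full(h.size, eps_flat[0])
    return np.asarray(relative_permittivity(_face_field(state.phi, h), params))
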