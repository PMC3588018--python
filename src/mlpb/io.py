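"""Structured output: profile tables and run summaries.

Profiles go to a delimited text table (schema below, frozen at version 1)
with 12 significant digits so a round-trip through the file reproduces the
values at the stated precision; scalar results and the resolved
configuration go to a YAML summary document next to it.

Column schema (version 1, fixed order)::

    x_nm, phi_mV, eps_r, n_plus_mol_per_l, n_minus_mol_per_l,
    rho_ions_C_per_m3, rho_zw_C_per_m3, prob_density
"""

from __future__ import annotations

from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .constants import MOL_PER_L_TO_PER_M3, NM
from .observables import Profiles, SweepResult

PROFILE_COLUMNS = [
    "x_nm",
    "phi_mV",
    "eps_r",
    "n_plus_mol_per_l",
    "n_minus_mol_per_l",
    "rho_ions_C_per_m3",
    "rho_zw_C_per_m3",
    "prob_density",
]

_FLOAT_FMT = "%.12g"
SCHEMA_VERSION = 1


def profiles_frame(profiles: Profiles) -> pd.DataFrame:
    """Profiles as a DataFrame in user units (nm, mV, mol/l, C/m^3)."""
    return pd.DataFrame(
        {
            "x_nm": profiles.x / NM,
            "phi_mV": profiles.phi * 1e3,
            "eps_r": profiles.eps_r,
            "n_plus_mol_per_l": profiles.n_plus / MOL_PER_L_TO_PER_M3,
            "n_minus_mol_per_l": profiles.n_minus / MOL_PER_L_TO_PER_M3,
            "rho_ions_C_per_m3": profiles.rho_ions,
            "rho_zw_C_per_m3": profiles.rho_zw,
            "prob_density": profiles.prob_density,
        },
        columns=PROFILE_COLUMNS,
    )


def write_profiles(profiles: Profiles, path: str | Path) -> None:
    """Write the profile table as tab-delimited text with a header row."""
    frame = profiles_frame(profiles)
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_profiles(path: str | Path) -> pd.DataFrame:
    """Read back a profile table written by :func:`write_profiles`."""
    return pd.read_csv(path, sep="\t")


def sweep_frame(sweep: SweepResult) -> pd.DataFrame:
    """Temperature sweep as a DataFrame in user units."""
    return pd.DataFrame(
        {
            "t_kelvin": sweep.temperatures,
            "a0_nm2": sweep.a0 / NM**2,
            "phase": sweep.phase,
            "mean_omega_deg": sweep.mean_omega_deg,
            "phi_surface_mV": sweep.phi_surface * 1e3,
            "eps_r_surface": sweep.eps_surface,
        }
    )


def write_sweep(sweep: SweepResult, path: str | Path) -> None:
    """Write the per-temperature summary table (tab-delimited)."""
    sweep_frame(sweep).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_summary(
    config_echo: dict,
    *,
    converged: bool,
    iterations: int,
    final_residual: float,
    phi_surface_mV: float,
    eps_r_surface: float,
    eps_r_far: float,
    lambda_norm: float,
    mean_omega_deg: float | None = None,
) -> dict:
    """Assemble the serializable run summary.

    The config echo is the fully resolved configuration, sufficient to
    rerun the computation exactly; provenance adds the package version and
    a UTC timestamp.
    """
    return {
        "schema_version": SCHEMA_VERSION,
        "config": config_echo,
        "convergence": {
            "converged": bool(converged),
            "iterations": int(iterations),
            "final_residual_V": float(final_residual),
        },
        "results": {
            "phi_surface_mV": float(phi_surface_mV),
            "eps_r_surface": float(eps_r_surface),
            "eps_r_far": float(eps_r_far),
            "lambda_norm": float(lambda_norm),
            **(
                {"mean_omega_deg": float(mean_omega_deg)}
                if mean_omega_deg is not None
                else {}
            ),
        },
        "provenance": {
            "package": f"mlpb {__version__}",
            "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        },
    }


def write_summary(summary: dict, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)


def read_summary(path: str | Path) -> dict:
    with Path(path).open() as fh:
        return yaml.safe_load(fh)
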