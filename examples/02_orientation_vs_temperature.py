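"""Average headgroup tilt across the DPPC gel/liquid transition.

Sweeps temperature through both phases (the 314 K transition point itself
is excluded: the model has no transition physics) and prints the mean
angle <omega> between the P-N headgroup dipole and the membrane normal.
"""

from mlpb import dppc_gel, temperature_sweep

sweep = temperature_sweep(dppc_gel(), [300, 305, 310, 318, 323, 330])

print(" T (K)  phase    a0 (nm^2)  <omega> (deg)  phi(0) (mV)")
for T, ph, a0, om, phi in zip(
    sweep.temperatures, sweep.phase, sweep.a0, sweep.mean_omega_deg, sweep.phi_surface
):
    print(f"{T:6.0f}  {ph:7s}  {a0 * 1e18:8.2f}  {om:12.2f}  {phi * 1e3:10.2f}")

print(
    "\nWithin each phase the angle is temperature-independent; the step at "
    "314 K comes entirely from the change in area per lipid. A uniform "
    "distribution would give 57.30 deg, so both phases have the positive "
    "charge pulled toward the negatively charged plane (dipole tilted flat)."
)
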