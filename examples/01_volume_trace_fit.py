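"""Simulate one cell's osmotic volume response and re-fit its parameters.

A round cell equilibrated at 333 mOsm/liter is hit with a hyperosmotic
step to 466 mOsm (it shrinks) and then a hypo-osmotic step back to 333
(it reswells), 5 minutes each, sampled at 0.5 Hz.  The Kedem–Katchalsky
mixture-model fit recovers the hydraulic permeability L_p and the
osmotically active water fraction φ_ir for each step independently.
"""

from cytomech import (
    CellParams,
    ModelConstants,
    OsmoticProtocol,
    fit_two_step_sequence,
    simulate_volume_response,
)

params = CellParams(
    lp=(7.2e-14, 8.8e-14),  # hyper-/hypo-osmotic L_p, m³/(N·s)
    phi_ir=0.6,             # 60% of the reference volume is active water
    radius_ref=9.1e-6,      # m
    c_ir=333.0,             # mOsm/liter at equilibration
)
protocol = OsmoticProtocol.default()
constants = ModelConstants()

trace = simulate_volume_response(params, protocol, constants)
v0 = trace.volume[0]
print(f"reference volume: {v0:.3e} m^3")
print(f"volume after shrinking step: {trace.volume[trace.step_index == 0][-1] / v0:.4f} x V_r")

for fit in fit_two_step_sequence(trace, protocol, constants):
    print(
        f"{fit.step_label:>5} step: Lp = {fit.lp:.3e} m^3/(N.s), "
        f"phi_ir = {fit.phi_ir:.3f}, R^2 = {fit.r_squared:.5f}"
    )

# The hyper step should return Lp ≈ 7.2e-14 and phi_ir ≈ 0.6 — the fit is
# exact on noiseless data.  The hypo step's phi_ir is lower because the
# reference state is the shrunken cell, which has proportionally more
# solid volume.
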