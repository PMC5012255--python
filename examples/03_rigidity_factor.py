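"""Compute the viscoelastic model outputs for a forming clot.

From the shift curves the model derives effective elasticity mu_t,
effective mass density M_t and their ratio, the rigidity factor RF.
For a given clot RF(t) settles to a roughly constant value that
characterises how rigid the attached fibrin is.
"""

from clotqcm import (
    ClotSimParams,
    rigidity_series,
    rigidity_summary,
    simulate_shift_series,
)

series, _ = simulate_shift_series(ClotSimParams(A_f=1100.0, A_g=1236.068, seed=2))
vs = rigidity_series(series)

for i in range(0, series.t.size, 200):
    rf = f"{vs.RF[i]:.4f}" if vs.defined[i] else "undefined"
    print(f"t = {vs.t[i]:6.0f} s   c = {vs.c[i]:.3f}   mu_t = {vs.mu_t[i]:7.4f}"
          f"   M_t = {vs.M_t[i]:7.4f}   RF = {rf}")

mu, M, rf = rigidity_summary(vs)  # mean over the last 20% of the trace
print(f"\nplateau summary: mu_t = {mu:.3f}, M_t = {M:.3f}, RF = {rf:.3f}")
# mu_t and M_t are exactly zero at sample loading (the z-snapshot) and
# grow as fibrin couples to the sensor; RF is their ratio, undefined at
# onset (0/0 guard) and near-constant once the clot is established.
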