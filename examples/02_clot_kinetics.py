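"""Extract coagulation kinetics from a clot-formation shift curve.

Simulates a plasma clot forming on the sensor (sigmoidal frequency and
bandwidth shifts on top of the liquid-loading plateau, light noise) and
extracts the four kinetic parameters per channel.
"""

from clotqcm import ClotSimParams, extract_kinetics, simulate_shift_series

params = ClotSimParams(A_f=2000.0, A_g=1800.0, k=0.02, t0=400.0, noise_sd=10.0, seed=1)
series, truth = simulate_shift_series(params)

for channel in ("f", "gamma"):
    kp = extract_kinetics(series, channel, smooth_window=151, presmooth=True)
    t = truth[kp.channel]
    print(f"{kp.channel:9s}  max = {kp.max_shift:7.1f} Hz (true {t.max_shift:.0f})"
          f"  R = {kp.R_qcm:6.1f} s (true {t.R_qcm:.1f})"
          f"  MRCF = {kp.MRCF:5.2f} Hz/s (true {t.MRCF:.2f})"
          f"  TMRCF = {kp.TMRCF:5.0f} s (true {t.TMRCF:.0f})")
# R is the clotting time (10% of the maximum starred response), MRCF the
# peak rate of clot formation from the smoothed first derivative, TMRCF
# the time of that peak.  Faster activation -> shorter R/TMRCF, higher MRCF.
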