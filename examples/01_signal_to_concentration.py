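"""From SPGR signals to gadolinium concentration.

Synthesises noiseless spoiled-gradient-echo signals for a tissue with known
T1 and a known contrast-agent concentration course, estimates T1 from the
two flip-angle volumes, and inverts the dynamic signal back to
concentration. On noiseless input the chain is exact.
"""

import numpy as np

from bbbleak import (AcquisitionParams, SignalCurve, concentration_from_signal,
                     fit_vfa_t1, spgr_signal)

acq = AcquisitionParams()  # TR 8.24 ms, flips 2/12 deg, 20 frames at 73 s
t10_ms, m0 = 1100.0, 800.0
conc_true = np.array([0.0, 0.12, 0.45, 0.38, 0.30, 0.26, 0.24, 0.22])

# pre-contrast VFA pair -> T1 estimate
s_low = spgr_signal(m0, t10_ms, acq.flip_low_deg, acq.tr_ms)
s_high = spgr_signal(m0, t10_ms, acq.flip_high_deg, acq.tr_ms)
t1_est = fit_vfa_t1(s_low, s_high, acq)
print(f"VFA T1 estimate: {t1_est.t10_ms:.1f} ms (truth {t10_ms}), "
      f"m0 {t1_est.m0:.1f} (truth {m0})")

# dynamic signal implied by the concentration course (r1 shortens T1)
t1_t = 1000.0 / (1000.0 / t10_ms + acq.r1_per_s_mM * conc_true)
signal = spgr_signal(m0, t1_t, acq.flip_high_deg, acq.tr_ms)
curve = SignalCurve(np.arange(conc_true.size) * acq.frame_interval_s,
                    signal, signal[0])

conc = concentration_from_signal(curve, t1_est, acq)
print("recovered concentration (mM):", np.round(conc.conc_mM, 6))
print("max |error| vs truth (mM):", np.abs(conc.conc_mM - conc_true).max())
# The SPGR inversion uses only the signal ratio S_i/S_0, so scanner gain
# cancels; the recovered curve matches the generating one to round-off.
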