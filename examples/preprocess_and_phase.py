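"""From a raw two-hand recording to the relative-phase summary.

Builds a synthetic pose-tracked trial (elliptical fingertip paths, drift,
jitter, tracking dropouts), runs the preprocessing chain (trim, mask,
interpolate, rotate, band-pass), and summarises coordination with the
length and angle of the resultant vector of the relative phase.
"""

import numpy as np

import tapdyn as td

params = td.HKBParams(a=1.0, b=1.0, delta_omega=0.0, Q=0.3,
                      carrier_freq=7.0, fs=59.94, duration=12.0, seed=42)
traj = td.simulate_relative_phase(params, phi0=np.pi)
profile = td.KinematicProfile(amplitude=60.0, axis_ratio=0.35,
                              orientation=0.5, center_drift_amp=8.0,
                              measurement_noise_sd=1.5, dropout_rate=0.03)
rec = td.synthesize_recording(traj, params, profile, seed=43)
print(f"raw recording: {rec.n_frames} frames at {rec.fs} Hz, "
      f"{int((rec.hands['left'].likelihood < 0.95).sum())} left-hand dropouts")

clean = td.preprocess_recording(rec)
print(f"analysis window: {clean.window[0]:.0f}-{clean.window[1]:.0f} s, "
      f"{len(clean.x_left)} frames")

theta_l = td.instantaneous_phase(clean.x_left)
theta_r = td.instantaneous_phase(clean.x_right)
series = td.relative_phase(theta_r, theta_l, fs=clean.fs)
summ = td.length_resultant_vector(series)

# ground truth from the generating phase series (same window)
phi_true = td.wrap_phase(traj.phi[60:60 + len(clean.x_left)])
truth = td.length_resultant_vector(td.RelativePhaseSeries(phi=phi_true,
                                                          fs=params.fs))

print(f"pipeline LRV      : {summ.lrv:.3f} at {summ.mean_angle_deg:+.1f} deg")
print(f"ground-truth LRV  : {truth.lrv:.3f} at {truth.mean_angle_deg:+.1f} deg")
print("LRV near 1 = consistent anti-phase tapping; the angle is the "
      "preferred relative phase (180 deg = hands alternating).")
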