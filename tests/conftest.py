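import numpy as np
import pandas as pd
import pytest

import tapdyn as td


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def anti_phase_recording():
    """Noiseless anti-phase trial: ground-truth relative phase is pi."""
    params = td.HKBParams(a=1.0, b=1.0, delta_omega=0.0, Q=0.0,
                          carrier_freq=7.0, fs=59.94, duration=12.0, seed=0)
    traj = td.simulate_relative_phase(params, phi0=np.pi)
    profile = td.KinematicProfile(measurement_noise_sd=0.0,
                                  center_drift_amp=0.0, dropout_rate=0.0,
                                  orientation=0.3)
    rec = td.synthesize_recording(traj, params, profile, seed=1,
                                  metadata={"participant": "pro00",
                                            "group": "professional",
                                            "trial": 1})
    return rec, traj


@pytest.fixture
def noisy_recording():
    """Realistic trial: phase noise, jitter, drift and dropouts."""
    params = td.HKBParams(a=1.0, b=1.0, delta_omega=0.0, Q=0.3,
                          carrier_freq=7.0, fs=59.94, duration=12.0, seed=7)
    traj = td.simulate_relative_phase(params, phi0=np.pi)
    profile = td.KinematicProfile(measurement_noise_sd=1.5,
                                  center_drift_amp=8.0, dropout_rate=0.05,
                                  orientation=-0.4)
    return td.synthesize_recording(traj, params, profile, seed=8,
                                   metadata={"participant": "ama00",
                                             "group": "amateur", "trial": 2})


def simulate_observation_table(rng, group_shift=0.0, n_per_group=8,
                               n_trials=3, sd_participant=1.0, sd_trial=0.3,
                               sd_resid=0.5, response="y"):
    """Observation table drawn from the mixed-model generative process."""
    rows = []
    trial_eff = rng.normal(0.0, sd_trial, n_trials)
    for g_idx, group in ((0, "amateur"), (1, "professional")):
        for p in range(n_per_group):
            u = rng.normal(0.0, sd_participant)
            for t in range(n_trials):
                rows.append({
                    "participant": f"{group[:3]}{p:02d}",
                    "group": group,
                    "trial": t + 1,
                    response: u + trial_eff[t] + g_idx * group_shift
                    + rng.normal(0.0, sd_resid),
                })
    return pd.DataFrame(rows)


@pytest.fixture
def observation_table(rng):
    return simulate_observation_table(rng, group_shift=2.0)
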