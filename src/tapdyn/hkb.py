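"""Stochastic Haken–Kelso–Bunz (HKB) relative-phase dynamics.

The HKB model describes bimanual coordination through the relative phase
``phi = theta_r - theta_l`` between the two hands::

    dphi/dt = delta_omega - a*sin(phi) - 2*b*sin(2*phi) + sqrt(Q)*xi(t)

with coupling strengths ``a`` and ``b`` (1/s), detuning ``delta_omega``
(rad/s, the difference between the hands' intrinsic frequencies), and a
Gaussian white-noise force of intensity ``Q`` (rad^2/s).  For
``delta_omega = 0`` the deterministic system has fixed points at
``phi = 0`` (in-phase) and ``phi = pi`` (anti-phase); the anti-phase
attractor loses stability when ``b/a`` drops below 1/4.

This module integrates the stochastic equation (Euler–Maruyama), provides
the analytic linear stability of the fixed points as an independent oracle,
and turns phase trajectories into realistic two-hand fingertip recordings
(elliptical paths, positional drift, measurement noise, tracking dropouts)
so the downstream analysis pipeline can be exercised without video data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .preprocess import HandTrack, RawRecording

__all__ = [
    "HKBParams",
    "PhaseTrajectory",
    "KinematicProfile",
    "drift",
    "simulate_relative_phase",
    "simulate_phase_ensemble",
    "fixed_point_stability",
    "synthesize_recording",
    "estimate_detuning",
]

#: likelihood values below this are treated as tracking dropouts downstream
LIKELIHOOD_THRESHOLD = 0.95

#: sub-steps of the SDE integrator per output frame
SUBSTEPS = 10


@dataclass(frozen=True)
class HKBParams:
    """Parameters of the stochastic HKB relative-phase equation.

    Parameters
    ----------
    a, b : float
        Coupling strengths (1/s); ``a >= 0``, ``b >= 0``.
    delta_omega : float
        Detuning (rad/s): difference between the hands' intrinsic
        oscillation frequencies.
    Q : float
        Intensity of the Gaussian white-noise force (rad^2/s).
    carrier_freq : float
        Common tapping frequency (Hz) used to reconstruct hand positions.
    fs : float
        Output sampling rate (Hz).
    duration : float
        Trial length (s).
    seed : int
        RNG seed; identical parameters and seed give bit-identical output.
    """

    a: float = 1.0
    b: float = 1.0
    delta_omega: float = 0.0
    Q: float = 0.0
    carrier_freq: float = 7.0
    fs: float = 59.94
    duration: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        vals = (self.a, self.b, self.delta_omega, self.Q,
                self.carrier_freq, self.fs, self.duration)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("HKB parameters must be finite")
        if self.a < 0 or self.b < 0 or self.Q < 0:
            raise ValueError("a, b and Q must be non-negative")
        if self.fs <= 0 or self.duration <= 0 or self.carrier_freq <= 0:
            raise ValueError("fs, duration and carrier_freq must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass(frozen=True)
class PhaseTrajectory:
    """Relative-phase trajectory phi(t), unwrapped, sampled at ``fs``."""

    t: np.ndarray
    phi: np.ndarray
    phi0: float

    def __post_init__(self) -> None:
        if len(self.t) != len(self.phi):
            raise ValueError("t and phi must have equal length")


@dataclass(frozen=True)
class KinematicProfile:
    """Geometry and noise of a synthetic fingertip trajectory.

    Fingertip paths during fast tapping are roughly elliptical; the tap
    point sits at the positive end of the major axis.  Pose-estimation
    output additionally shows slow positional drift, frame-to-frame
    jitter, and occasional low-confidence (dropout) frames.
    """

    amplitude: float = 50.0          # major-axis half-length (px)
    axis_ratio: float = 0.35         # minor/major, in [0, 1]
    orientation: float = 0.0         # ellipse rotation (rad)
    center: tuple[float, float] = (0.0, 0.0)
    center_drift_amp: float = 5.0    # low-frequency drift amplitude (px)
    drift_freq: float = 0.3          # drift frequency (Hz)
    measurement_noise_sd: float = 1.0  # additive position noise (px)
    dropout_rate: float = 0.0        # fraction of low-likelihood frames
    tap_dwell: float = 0.3           # dwell asymmetry at the tap point, [0, 1)

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if not 0.0 <= self.axis_ratio <= 1.0:
            raise ValueError("axis_ratio must lie in [0, 1]")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.measurement_noise_sd < 0 or self.center_drift_amp < 0:
            raise ValueError("noise and drift amplitudes must be non-negative")
        if not 0.0 <= self.tap_dwell < 1.0:
            raise ValueError("tap_dwell must lie in [0, 1)")


def drift(phi: np.ndarray | float, params: HKBParams) -> np.ndarray | float:
    """Deterministic part of dphi/dt."""
    return (params.delta_omega
            - params.a * np.sin(phi)
            - 2.0 * params.b * np.sin(2.0 * phi))


def _check_step(params: HKBParams, dt: float) -> None:
    # Coarse drift bound; an explicit Euler step that can traverse more than
    # pi per step is numerically meaningless for this vector field.
    bound = abs(params.delta_omega) + params.a + 2.0 * params.b
    if bound * dt > np.pi:
        raise ValueError(
            f"integration step {dt:.3g}s unstable for drift bound "
            f"{bound:.3g}/s (|drift*dt| > pi); reduce dt or the couplings")


def simulate_relative_phase(params: HKBParams, phi0: float = np.pi) -> PhaseTrajectory:
    """Integrate the stochastic HKB equation by Euler–Maruyama.

    The SDE is stepped at ``dt = 1/(SUBSTEPS*fs)`` and decimated to the
    output rate ``fs``; the noise increment per step is
    ``sqrt(Q*dt)*N(0,1)``.  With ``Q = 0`` this reduces to deterministic
    Euler integration of the drift.  The returned phase is unwrapped.
    """
    if not math.isfinite(phi0):
        raise ValueError("phi0 must be finite")
    dt = 1.0 / (SUBSTEPS * params.fs)
    _check_step(params, dt)
    n_out = params.n_frames
    rng = np.random.default_rng(params.seed)
    n_steps = n_out * SUBSTEPS
    if params.Q > 0:
        noise = rng.standard_normal(n_steps) * math.sqrt(params.Q * dt)
    else:
        noise = np.zeros(n_steps)
    phi = np.empty(n_out)
    p = float(phi0)
    a, b, dw = params.a, params.b, params.delta_omega
    k = 0
    for i in range(n_out):
        for _ in range(SUBSTEPS):
            p += (dw - a * math.sin(p) - 2.0 * b * math.sin(2.0 * p)) * dt + noise[k]
            k += 1
        phi[i] = p
    t = (np.arange(n_out) + 1) / params.fs
    return PhaseTrajectory(t=t, phi=phi, phi0=float(phi0))


def simulate_phase_ensemble(params: HKBParams, phi0: float, n_rep: int) -> np.ndarray:
    """Vectorised Euler–Maruyama over ``n_rep`` independent replicates.

    Returns an array of shape ``(n_rep, n_frames)`` with the decimated
    phase trajectories.  Used for diffusion/variance checks where a large
    number of replicates is needed.
    """
    dt = 1.0 / (SUBSTEPS * params.fs)
    _check_step(params, dt)
    n_out = params.n_frames
    rng = np.random.default_rng(params.seed)
    p = np.full(n_rep, float(phi0))
    out = np.empty((n_rep, n_out))
    a, b, dw = params.a, params.b, params.delta_omega
    sq = math.sqrt(params.Q * dt)
    for i in range(n_out):
        for _ in range(SUBSTEPS):
            p = p + (dw - a * np.sin(p) - 2.0 * b * np.sin(2.0 * p)) * dt
            if sq > 0:
                p = p + sq * rng.standard_normal(n_rep)
        out[:, i] = p
    return out


def fixed_point_stability(params: HKBParams, phi_star: float,
                          tol: float = 1e-6) -> tuple[bool, float]:
    """Linear stability of a candidate fixed point of the drift.

    Returns ``(is_fixed_point, eigenvalue)`` where the eigenvalue is the
    derivative of the drift at ``phi_star``::

        lambda = -a*cos(phi*) - 4*b*cos(2*phi*)

    Negative eigenvalue means the fixed point is stable.  If the drift at
    ``phi_star`` exceeds ``tol`` the point is flagged as not a fixed point
    but the eigenvalue is still reported.
    """
    d = float(drift(phi_star, params))
    eig = -params.a * math.cos(phi_star) - 4.0 * params.b * math.cos(2.0 * phi_star)
    return (abs(d) <= tol), eig


def _ellipse_xy(theta: np.ndarray, profile: KinematicProfile) -> tuple[np.ndarray, np.ndarray]:
    # Tap point at theta = 0 (positive end of the major axis).  The phase
    # warp theta - tap_dwell*sin(theta) slows the fingertip near the tap
    # point, emulating the dwell at drum contact; this asymmetry is what
    # lets the rotation stage orient the tap cluster to positive x.
    theta = theta - profile.tap_dwell * np.sin(theta)
    xa = profile.amplitude * np.cos(theta)
    ya = profile.amplitude * profile.axis_ratio * np.sin(theta)
    c, s = math.cos(profile.orientation), math.sin(profile.orientation)
    return c * xa - s * ya, s * xa + c * ya


def synthesize_recording(traj: PhaseTrajectory, params: HKBParams,
                         profile_left: KinematicProfile,
                         profile_right: KinematicProfile | None = None,
                         seed: int = 0,
                         metadata: dict | None = None) -> RawRecording:
    """Turn a relative-phase trajectory into a two-hand fingertip recording.

    The left hand carries the common tapping rhythm,
    ``theta_l(t) = 2*pi*carrier_freq*t``; the right hand leads it by the
    simulated relative phase, ``theta_r = theta_l + phi(t)``.  Each hand's
    planar position is a point on its ellipse at its phase, plus sinusoidal
    centre drift and Gaussian measurement noise.  A seeded random subset of
    ``round(dropout_rate*N)`` frames per hand receives a likelihood drawn
    uniformly from ``[0, 0.95)``; all other frames have likelihood 1.
    """
    if len(traj.phi) != params.n_frames:
        raise ValueError("trajectory length does not match params.fs*duration")
    if profile_right is None:
        profile_right = profile_left
    rng = np.random.default_rng(seed)
    t = traj.t
    theta_l = 2.0 * np.pi * params.carrier_freq * t
    theta_r = theta_l + traj.phi
    hands = {}
    for label, theta, prof in (("left", theta_l, profile_left),
                               ("right", theta_r, profile_right)):
        x, y = _ellipse_xy(theta, prof)
        if prof.center_drift_amp > 0:
            dphase = rng.uniform(0, 2 * np.pi, size=2)
            x = x + prof.center_drift_amp * np.sin(2 * np.pi * prof.drift_freq * t + dphase[0])
            y = y + prof.center_drift_amp * np.sin(2 * np.pi * prof.drift_freq * t + dphase[1])
        x = x + prof.center[0]
        y = y + prof.center[1]
        if prof.measurement_noise_sd > 0:
            x = x + rng.normal(0, prof.measurement_noise_sd, size=len(t))
            y = y + rng.normal(0, prof.measurement_noise_sd, size=len(t))
        likelihood = np.ones(len(t))
        n_drop = int(round(prof.dropout_rate * len(t)))
        if n_drop:
            idx = rng.choice(len(t), size=n_drop, replace=False)
            likelihood[idx] = rng.uniform(0.0, LIKELIHOOD_THRESHOLD, size=n_drop)
        hands[label] = HandTrack(x=x, y=y, likelihood=likelihood)
    return RawRecording(fs=params.fs, hands=hands, metadata=dict(metadata or {}))


def estimate_detuning(freq_left: float, freq_right: float) -> float:
    """Detuning estimate from unimanual tapping frequencies (Hz).

    The absolute difference between the left and right hands' solo tapping
    frequencies; larger values destabilise bimanual coordination.
    """
    if freq_left <= 0 or freq_right <= 0:
        raise ValueError("frequencies must be positive")
    return abs(freq_left - freq_right)
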