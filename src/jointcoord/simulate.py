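"""Synthetic movement generators for validating the coordination metrics.

Two generators are provided:

* :func:`make_sine_datasets` — a pair of two-joint sinusoid datasets
  that differ only in the phase lag of the second joint.  The analytic
  covariance and phase structure of sinusoids make every downstream
  quantity checkable in closed form.
* :func:`make_reaching_dataset` — a planar two-link arm (shoulder
  flexion, elbow flexion) reaching targets at several heights with one
  of four named coordination strategies.  The task is 1-DoF (reach a
  height) executed with 2 joints, so strategies can trade joint
  contributions and timing against each other while still completing
  the task:

  - ``physiological``: both joints move together with a
    proximal-to-distal lead (shoulder starts first, elbow finishes),
    sharing the excursion with a shoulder-dominant ratio;
  - ``desync``: the same start and end postures, but strictly
    sequential — all shoulder flexion first, then all elbow extension;
  - ``shoulder_only``: the elbow is held at its start angle and the
    shoulder alone solves the height;
  - ``elbow_overuse``: the shoulder repeats its physiological
    trajectory while the elbow first flexes then extends, taking a
    non-monotone detour to the same final angle.

Hand-height trajectories follow a minimum-jerk profile (the standard
smoothness model for point-to-point reaching).  Per-repetition start
jitter, duration jitter and Gaussian measurement noise emulate the
variability of a human wearing encoder-instrumented hardware.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .dataio import Dataset, MovementRepetition

__all__ = [
    "SineSpec",
    "ArmSpec",
    "STRATEGIES",
    "make_sine_datasets",
    "forward_kinematics",
    "make_reaching_dataset",
]

STRATEGIES = ("physiological", "desync", "shoulder_only", "elbow_overuse")


@dataclass
class SineSpec:
    """Two-sine validation pair: theta1 = a sin(wt) in both datasets;
    theta2 = ratio * a sin(wt + shift) with a different shift per
    dataset.  Defaults: unit amplitude, doubled second joint, shifts of
    1 rad and pi/2 rad, a 1 Hz oscillation recorded for 5 s at 100 Hz.
    """

    amplitude: float = 1.0
    amplitude_ratio: float = 2.0
    phase_shift_a: float = 1.0
    phase_shift_b: float = np.pi / 2
    frequency: float = 1.0
    duration: float = 5.0
    sample_rate: float = 100.0
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sample_rate <= 2 * self.frequency:
            raise ValueError("sample_rate must exceed twice the frequency")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def _sine_dataset(spec: SineSpec, shift: float, name: str, rng: np.random.Generator) -> Dataset:
    # samples cover [0, duration) so whole-period runs have zero-mean joints
    t = np.arange(0.0, spec.duration, 1.0 / spec.sample_rate)
    w = 2 * np.pi * spec.frequency
    theta1 = spec.amplitude * np.sin(w * t)
    theta2 = spec.amplitude_ratio * spec.amplitude * np.sin(w * t + shift)
    ang = np.column_stack([theta1, theta2])
    if spec.noise_sd > 0:
        ang = ang + rng.normal(0.0, spec.noise_sd, ang.shape)
    rep = MovementRepetition(t, ang, ["theta1", "theta2"], {"condition": name})
    return Dataset(name=name, repetitions=[rep], joint_names=["theta1", "theta2"],
                   angle_unit="rad")


def make_sine_datasets(spec: SineSpec = SineSpec()) -> tuple[Dataset, Dataset]:
    """The two-sine dataset pair (A, B).  The first joint is identical
    in both; the second differs only in phase lag, so dataset A has
    correlated joints (cov ~ cos(shift_a)) while dataset B's quarter-
    period lag makes them uncorrelated."""
    rng = np.random.default_rng(spec.seed)
    a = _sine_dataset(spec, spec.phase_shift_a, "A", rng)
    b = _sine_dataset(spec, spec.phase_shift_b, "B", rng)
    return a, b


@dataclass
class ArmSpec:
    """Planar 2-link arm and reaching protocol.

    Angle convention (degrees): shoulder flexion ``theta1`` measured
    from the vertical-down rest direction (0 = arm hanging, 90 = arm
    horizontal forward); elbow flexion ``theta2`` as the interior angle
    between upper arm and forearm (180 = straight arm).  Hand height is
    relative to the shoulder.  Default segment lengths are adult
    upper-arm/forearm values; targets are heights requiring distinct
    joint excursions from the rest posture (arm hanging, elbow at a
    comfortable 140 degrees).
    """

    upper_arm_length: float = 0.30
    forearm_length: float = 0.28
    start_shoulder: float = 0.0
    start_elbow: float = 140.0
    target_heights: tuple[float, ...] = (-0.15, 0.0, 0.15)
    reps_per_target: int = 5
    strategy: str = "physiological"
    movement_duration: float = 2.0
    sample_rate: float = 100.0
    noise_sd: float = 0.05
    start_jitter_sd: float = 1.0
    duration_jitter: float = 0.1
    elbow_share: float = 0.25
    overuse_flexion: float = 15.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.movement_duration <= 0 or self.sample_rate <= 0:
            raise ValueError("durations and rates must be positive")


def forward_kinematics(shoulder_flex: float, elbow_flex: float, arm: ArmSpec) -> float:
    """Hand height (m, relative to the shoulder) of the planar chain.

    With the convention above the forearm direction deviates from the
    upper-arm direction by the elbow's deficit from straight, so

        height = -L1 cos(t1) - L2 cos(t1 + (180 - t2))

    (angles in degrees).  Accepts scalars or arrays.
    """
    t1 = np.deg2rad(shoulder_flex)
    t2 = np.deg2rad(elbow_flex)
    return -arm.upper_arm_length * np.cos(t1) - arm.forearm_length * np.cos(
        t1 + (np.pi - t2)
    )


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0, 1], clipped outside."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _solve_excursion(arm: ArmSpec, start1: float, start2: float, target: float,
                     elbow_ratio: float) -> float:
    """Shoulder excursion D such that the posture (start1 + D,
    start2 + elbow_ratio*D) puts the hand at the target height.
    The elbow is capped near straight; raises if the target is out of
    reach along this joint-sharing path."""
    d_max = 130.0
    if elbow_ratio > 0:
        d_max = min(d_max, (175.0 - start2) / elbow_ratio)

    def height_err(d: float) -> float:
        return forward_kinematics(start1 + d, start2 + elbow_ratio * d, arm) - target

    lo, hi = height_err(0.0), height_err(d_max)
    if lo * hi > 0:
        raise ValueError(
            f"target height {target} m is unreachable with strategy sharing "
            f"ratio {elbow_ratio} from ({start1:.1f}, {start2:.1f}) deg"
        )
    return brentq(height_err, 0.0, d_max)


def _strategy_profiles(strategy: str, tau: np.ndarray, d_sh: float, d_el: float,
                       overuse_flexion: float) -> tuple[np.ndarray, np.ndarray]:
    """Joint excursion time-courses (relative to the start posture) for
    one repetition, given total shoulder/elbow excursions."""
    if strategy == "physiological":
        # proximal-to-distal overlap: shoulder leads, elbow trails
        sh = d_sh * _min_jerk(tau / 0.85)
        el = d_el * _min_jerk((tau - 0.15) / 0.85)
        return sh, el
    if strategy == "elbow_overuse":
        # shoulder repeats its physiological movement; the elbow first
        # flexes quickly, then performs one large extension to the same
        # final angle, synchronized with the shoulder's main rise
        sh = d_sh * _min_jerk(tau / 0.85)
        el = -overuse_flexion * _min_jerk(tau / 0.2) + (
            overuse_flexion + d_el
        ) * _min_jerk((tau - 0.2) / 0.8)
        return sh, el
    if strategy == "desync":
        sh = d_sh * _min_jerk(tau / 0.5)
        el = d_el * _min_jerk((tau - 0.5) / 0.5)
        return sh, el
    if strategy == "shoulder_only":
        return d_sh * _min_jerk(tau), np.zeros_like(tau)
    raise ValueError(strategy)


def make_reaching_dataset(arm: ArmSpec) -> Dataset:
    """Simulate one condition: every target reached ``reps_per_target``
    times with the spec's strategy, in degrees, with per-repetition
    start/duration jitter and Gaussian measurement noise.

    Each repetition's joint excursions are solved from its own
    (jittered) start posture so the hand ends on the target, then
    played out along the strategy's timing profiles.
    """
    rng = np.random.default_rng(arm.seed)
    target_labels = [f"target{i + 1}" for i in range(len(arm.target_heights))]
    reps: list[MovementRepetition] = []
    for label, h in zip(target_labels, arm.target_heights):
        for r in range(arm.reps_per_target):
            s1 = arm.start_shoulder + rng.normal(0, arm.start_jitter_sd)
            s2 = arm.start_elbow + rng.normal(0, arm.start_jitter_sd)
            ratio = 0.0 if arm.strategy == "shoulder_only" else arm.elbow_share
            d_sh = _solve_excursion(arm, s1, s2, h, ratio)
            d_el = ratio * d_sh
            dur = arm.movement_duration * (
                1 + rng.uniform(-arm.duration_jitter, arm.duration_jitter)
            )
            n_t = max(int(round(dur * arm.sample_rate)) + 1, 3)
            t = np.arange(n_t) / arm.sample_rate
            tau = t / t[-1]
            sh, el = _strategy_profiles(
                arm.strategy, tau, d_sh, d_el, arm.overuse_flexion
            )
            ang = np.column_stack([s1 + sh, s2 + el])
            if arm.noise_sd > 0:
                ang = ang + rng.normal(0, arm.noise_sd, ang.shape)
            reps.append(
                MovementRepetition(
                    t,
                    ang,
                    ["shoulder_flex", "elbow_flex"],
                    {
                        "condition": arm.strategy,
                        "target": label,
                        "repetition": r + 1,
                        "target_height_m": h,
                    },
                )
            )
    return Dataset(
        name=arm.strategy,
        repetitions=reps,
        joint_names=["shoulder_flex", "elbow_flex"],
        angle_unit="deg",
    )
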