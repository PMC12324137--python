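"""JsvCRP: joint-synchronization variation via continuous relative phase.

For each joint of each movement repetition, position and velocity are
range-normalized to ``[-1, 1]`` and plotted against each other (the
phase portrait); the phase angle is the angle of the portrait point
above the horizontal (zero-velocity) axis, obtained with the
quadrant-aware two-argument arctangent.  The continuous relative phase
(CRP) of a joint pair is the pointwise difference of the two phase
angles: positive values mean the second joint leads the first.

To compare two datasets, per-repetition CRP curves are normalized to
0-100 % of movement duration on a common grid, averaged within each
dataset, and the area between the two mean curves is integrated:

    JsvCRP(A, B) = integral of |mean_CRP_B - mean_CRP_A|

A larger area means the pair's synchronization pattern changed more
between the conditions.  The area is symmetric in dataset order and
zero only when the mean curves coincide.

Range normalization amplifies noise on near-static joints, so a noise
guard compares the supplied noise range against a joint's range of
motion and substitutes an identically zero signal (phase 0) when noise
dominates: the joint is treated as not synchronizing with anything.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .dataio import Dataset, MovementRepetition

__all__ = [
    "PhasePortrait",
    "CRPCurve",
    "JsvCRPResult",
    "range_normalize",
    "estimate_velocity",
    "noise_ratio_guard",
    "phase_angle",
    "phase_portrait",
    "crp",
    "crp_curve",
    "time_normalize",
    "dtw_align",
    "mean_crp",
    "jsvcrp",
    "jsvcrp_all_pairs",
]

DEFAULT_GRID = 101  # 0, 1, ..., 100 % of movement duration


@dataclass
class PhasePortrait:
    """Normalized position/velocity trajectory of one joint and its
    phase angle; ``contributing`` is False when the noise guard zeroed
    the joint."""

    theta_norm: np.ndarray
    dtheta_norm: np.ndarray
    phase: np.ndarray
    joint: str
    contributing: bool = True


@dataclass
class CRPCurve:
    """Relative-phase curve of an ordered joint pair.

    ``grid`` is either raw time in seconds or the 0-100 % normalized
    axis (``normalized`` tells which); ``values`` are radians.
    """

    grid: np.ndarray
    values: np.ndarray
    pair: tuple[str, str]
    normalized: bool = False
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.values):
            raise ValueError("grid and values must have equal length")


@dataclass
class JsvCRPResult:
    """Areas between mean CRP curves for every joint pair of two
    datasets, with the mean curves that produced them."""

    areas: dict[tuple[str, str], float]
    mean_curves: dict[tuple[str, str], tuple[CRPCurve, CRPCurve]]
    unit: str  # e.g. "rad*%", "deg*%", "rad*s"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"joint_i": i, "joint_j": j, "area": a, "unit": self.unit}
            for (i, j), a in self.areas.items()
        ]
        return pd.DataFrame(rows)


def range_normalize(x: np.ndarray) -> np.ndarray:
    """Map ``x`` linearly onto ``[-1, 1]``: the minimum to -1 and the
    maximum to +1 exactly.  Constant input is an error — apply the
    noise guard first for joints that barely move."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise ValueError("cannot range-normalize a constant signal")
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def estimate_velocity(rep: MovementRepetition, joint: str) -> np.ndarray:
    """Joint angular velocity in angle-units per second.

    Central differences on the interior, second-order one-sided at the
    endpoints (``numpy.gradient`` on the repetition's own, possibly
    non-uniform, time base).
    """
    if rep.time is None:
        raise ValueError("velocity estimation needs a time vector")
    if rep.n_samples < 3:
        raise ValueError("need at least 3 samples to estimate velocity")
    return np.gradient(rep.joint(joint), rep.time, edge_order=2)


def noise_ratio_guard(x: np.ndarray, noise_range: float) -> str:
    """Decide whether a joint's signal is meaningful for phase analysis.

    Returns ``"keep"`` when the noise range is at most the range of
    motion, ``"zero_substitute"`` when noise exceeds it — in which case
    the joint's normalized position, velocity and phase are all set to
    zero and the joint flagged non-contributing.
    """
    if noise_range < 0:
        raise ValueError("noise_range must be >= 0")
    x = np.asarray(x, dtype=float)
    rom = x.max() - x.min()
    if rom == 0 or noise_range / rom > 1.0:
        return "zero_substitute"
    return "keep"


def phase_angle(theta_norm: np.ndarray, dtheta_norm: np.ndarray) -> np.ndarray:
    """Phase-portrait angle in radians, range ``(-pi, pi]``.

    The two-argument arctangent of (velocity, position): velocity is
    the ordinate, position the abscissa, so (1, 0) -> 0 and
    (0, 1) -> pi/2.  The degenerate origin point maps to 0.
    """
    phi = np.arctan2(dtheta_norm, theta_norm)
    # arctan2 yields [-pi, pi]; fold the -pi edge onto +pi
    phi = np.where(phi == -np.pi, np.pi, phi)
    return phi


def phase_portrait(
    rep: MovementRepetition, joint: str, noise_range: float = 0.0
) -> PhasePortrait:
    """Build a joint's normalized phase portrait for one repetition,
    applying the noise guard before range normalization."""
    theta = rep.joint(joint)
    if noise_ratio_guard(theta, noise_range) == "zero_substitute":
        z = np.zeros(rep.n_samples)
        return PhasePortrait(z, z.copy(), z.copy(), joint, contributing=False)
    vel = estimate_velocity(rep, joint)
    theta_n = range_normalize(theta)
    vel_n = range_normalize(vel)
    return PhasePortrait(theta_n, vel_n, phase_angle(theta_n, vel_n), joint)


def _wrap(d: np.ndarray) -> np.ndarray:
    """Wrap angles into ``(-pi, pi]``."""
    out = np.mod(d + np.pi, 2 * np.pi) - np.pi
    return np.where(out == -np.pi, np.pi, out)


def crp(phase_i: np.ndarray, phase_j: np.ndarray, unwrap: bool = False) -> np.ndarray:
    """Continuous relative phase ``phi_j - phi_i`` of a joint pair.

    Positive values mean the second joint leads.  By default the
    wrapped phases are subtracted and the difference re-wrapped into
    ``(-pi, pi]``; with ``unwrap=True`` each phase is unwrapped along
    time first and the raw difference returned (it can then leave
    ``(-pi, pi]``).
    """
    phase_i = np.asarray(phase_i, float)
    phase_j = np.asarray(phase_j, float)
    if phase_i.shape != phase_j.shape:
        raise ValueError("phase vectors must have equal length")
    if unwrap:
        return np.unwrap(phase_j) - np.unwrap(phase_i)
    return _wrap(phase_j - phase_i)


def crp_curve(
    rep: MovementRepetition,
    pair: tuple[str, str],
    noise_range: float = 0.0,
    unwrap: bool = False,
) -> CRPCurve:
    """CRP curve of one repetition on its raw time axis."""
    pi_ = phase_portrait(rep, pair[0], noise_range)
    pj_ = phase_portrait(rep, pair[1], noise_range)
    values = crp(pi_.phase, pj_.phase, unwrap=unwrap)
    if rep.time is None:
        raise ValueError("CRP curves need a time vector")
    return CRPCurve(grid=rep.time - rep.time[0], values=values, pair=pair)


def time_normalize(
    curve: CRPCurve, G: int = DEFAULT_GRID, reference: CRPCurve | None = None
) -> CRPCurve:
    """Resample a raw-time CRP curve onto ``G`` equally spaced points
    spanning 0-100 % of movement duration (linear interpolation).

    With ``reference`` given, the curve is first aligned to the
    reference by dynamic time warping and the warped values are
    resampled; use this when movement phases occupy very different
    fractions of the repetitions' durations.
    """
    if len(curve.grid) < 2:
        raise ValueError("need at least 2 samples to time-normalize")
    if G < 2:
        raise ValueError("grid size must be >= 2")
    values = curve.values
    if reference is not None:
        values = dtw_align(values, reference.values)
    src = np.linspace(0.0, 100.0, len(values))
    grid = np.linspace(0.0, 100.0, G)
    return CRPCurve(
        grid=grid,
        values=np.interp(grid, src, values),
        pair=curve.pair,
        normalized=True,
    )


def dtw_align(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Warp ``x`` onto the time base of ``y`` by classic dynamic time
    warping with a squared-difference cost, returning for each index of
    ``y`` the mean of the ``x`` samples matched to it.

    O(len(x)*len(y)) dynamic programming; intended for curves already
    resampled to ~100 points.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    cost = (x[:, None] - y[None, :]) ** 2
    acc = np.full((nx, ny), np.inf)
    acc[0, 0] = cost[0, 0]
    for i in range(nx):
        for j in range(ny):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0:
                best = min(best, acc[i - 1, j])
            if j > 0:
                best = min(best, acc[i, j - 1])
            if i > 0 and j > 0:
                best = min(best, acc[i - 1, j - 1])
            acc[i, j] = cost[i, j] + best
    # backtrack
    i, j = nx - 1, ny - 1
    sums = np.zeros(ny)
    counts = np.zeros(ny)
    while True:
        sums[j] += x[i]
        counts[j] += 1
        if i == 0 and j == 0:
            break
        moves = []
        if i > 0 and j > 0:
            moves.append((acc[i - 1, j - 1], i - 1, j - 1))
        if i > 0:
            moves.append((acc[i - 1, j], i - 1, j))
        if j > 0:
            moves.append((acc[i, j - 1], i, j - 1))
        _, i, j = min(moves, key=lambda t: t[0])
    return sums / counts


def mean_crp(
    ds: Dataset,
    pair: tuple[str, str],
    G: int = DEFAULT_GRID,
    noise_range: float = 0.0,
    unwrap: bool = False,
    targets: str | None = None,
) -> CRPCurve:
    """Mean CRP curve of a dataset (pooling all repetitions and targets
    by default) with pointwise standard deviation.

    Each repetition's curve is computed on its own time base, resampled
    to the 0-100 % grid, then averaged pointwise.  Set ``targets`` to a
    target label to restrict the pooling to one target's repetitions.
    """
    reps = ds.repetitions
    if targets is not None:
        reps = [r for r in reps if str(r.meta.get("target")) == str(targets)]
        if not reps:
            raise ValueError(f"no repetitions with target {targets!r}")
    curves = np.vstack(
        [
            time_normalize(crp_curve(r, pair, noise_range, unwrap), G).values
            for r in reps
        ]
    )
    grid = np.linspace(0.0, 100.0, G)
    return CRPCurve(
        grid=grid,
        values=curves.mean(axis=0),
        pair=pair,
        normalized=True,
        sd=curves.std(axis=0, ddof=0),
    )


def _pair_ordered(ds: Dataset, pair: tuple[str, str]) -> tuple[str, str]:
    i, j = pair
    for name in (i, j):
        if name not in ds.joint_names:
            raise ValueError(f"joint {name!r} not in dataset {ds.name!r}")
    if ds.joint_names.index(i) > ds.joint_names.index(j):
        i, j = j, i
    return (i, j)


def _area(grid: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    return float(np.trapezoid(np.abs(b - a), grid))


def jsvcrp(
    ref: Dataset,
    cmp: Dataset,
    pair: tuple[str, str] | None = None,
    G: int = DEFAULT_GRID,
    noise_range: float = 0.0,
    unwrap: bool = False,
    normalize_time: bool = True,
    degrees: bool | None = None,
) -> float:
    """Area between the two datasets' mean CRP curves for one pair.

    The integral runs over the 0-100 % axis (trapezoidal rule), or over
    raw seconds with ``normalize_time=False`` when every repetition of
    both datasets shares one time base (e.g. single simulated signals).
    CRP values are radians internally; with ``degrees=True`` (the
    default when the datasets are recorded in degrees) the area is
    reported in deg x axis-unit instead.

    Symmetric in dataset order, non-negative, and zero when the mean
    curves coincide.
    """
    if degrees is None:
        degrees = ref.angle_unit == "deg"
    pair = _pair_ordered(ref, pair or tuple(ref.joint_names[:2]))
    _pair_ordered(cmp, pair)
    if normalize_time:
        ca = mean_crp(ref, pair, G, noise_range, unwrap)
        cb = mean_crp(cmp, pair, G, noise_range, unwrap)
        grid = ca.grid
    else:
        curves = {}
        for tag, ds in (("ref", ref), ("cmp", cmp)):
            per_rep = [crp_curve(r, pair, noise_range, unwrap) for r in ds.repetitions]
            grids = {tuple(np.round(c.grid, 12)) for c in per_rep}
            if len(grids) != 1:
                raise ValueError(
                    "normalize_time=False requires all repetitions on one time base"
                )
            vals = np.vstack([c.values for c in per_rep])
            curves[tag] = CRPCurve(
                per_rep[0].grid, vals.mean(axis=0), pair, sd=vals.std(axis=0)
            )
        ca, cb = curves["ref"], curves["cmp"]
        grid = ca.grid
        if len(cb.grid) != len(grid) or not np.allclose(cb.grid, grid):
            raise ValueError("datasets must share the time base when not normalizing")
    scale = 180.0 / np.pi if degrees else 1.0
    return _area(grid, scale * ca.values, scale * cb.values)


def jsvcrp_all_pairs(
    ref: Dataset,
    cmp: Dataset,
    G: int = DEFAULT_GRID,
    noise_range: float = 0.0,
    unwrap: bool = False,
    degrees: bool | None = None,
) -> JsvCRPResult:
    """JsvCRP areas for every joint pair (C(n,2) results), each with the
    two mean curves behind it, on the normalized 0-100 % axis."""
    if ref.joint_names != cmp.joint_names:
        raise ValueError("datasets must share joints")
    if degrees is None:
        degrees = ref.angle_unit == "deg"
    scale = 180.0 / np.pi if degrees else 1.0
    areas: dict[tuple[str, str], float] = {}
    mean_curves: dict[tuple[str, str], tuple[CRPCurve, CRPCurve]] = {}
    for pair in combinations(ref.joint_names, 2):
        ca = mean_crp(ref, pair, G, noise_range, unwrap)
        cb = mean_crp(cmp, pair, G, noise_range, unwrap)
        areas[pair] = _area(ca.grid, scale * ca.values, scale * cb.values)
        mean_curves[pair] = (ca, cb)
    return JsvCRPResult(
        areas=areas,
        mean_curves=mean_curves,
        unit=("deg" if degrees else "rad") + "*%",
    )
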