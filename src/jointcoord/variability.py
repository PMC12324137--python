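"""Natural-variability thresholds by repeated split-half comparison.

Both coordination-change metrics return a number even when nothing
changed, because human repetitions of one movement are never identical
("repetition without repetition").  To know how large a metric value
must be before it indicates a genuine strategy change, the baseline
condition's repetitions are shuffled and split in half, the metric is
computed between the halves, and the split is repeated many times.
The per-entry mean and dispersion over splits define the natural
variability of the metric for that task; observed values inside
mean +/- SE (or +/- SD) are inconclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import Dataset
from .jcvpca import jcvpca
from .jsvcrp import jsvcrp_all_pairs

__all__ = ["VariabilityThreshold", "natural_variability", "exceeds_threshold"]


@dataclass
class VariabilityThreshold:
    """Split-half distribution of a metric on one condition.

    ``mean``/``sd``/``se`` have the metric's own output shape: an
    ``m x n`` array for the PCA-based contribution metric, a dict over
    joint pairs for the CRP-based synchronization metric (stored as a
    1-D array aligned with ``entry_labels``).
    """

    metric: str
    mean: np.ndarray
    sd: np.ndarray
    se: np.ndarray
    entry_labels: list
    n_splits: int
    seed: int | None
    samples: np.ndarray  # n_splits x <entries>, the raw split values

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "n_splits": self.n_splits,
            "seed": self.seed,
            "entry_labels": [str(e) for e in self.entry_labels],
            "mean": self.mean.ravel().tolist(),
            "sd": self.sd.ravel().tolist(),
            "se": self.se.ravel().tolist(),
        }


def _split_indices(k: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Shuffle 0..k-1 and split; the reference half gets the extra
    repetition when k is odd.  Halves are disjoint and exhaustive."""
    perm = rng.permutation(k)
    half = (k + 1) // 2
    return perm[:half], perm[half:]


def natural_variability(
    ds: Dataset,
    metric: str = "jcvpca",
    n_splits: int = 15,
    seed: int | None = None,
    **metric_kwargs,
) -> VariabilityThreshold:
    """Distribution of a metric between random halves of one condition.

    Each iteration shuffles the repetitions with the seeded generator
    and partitions them into two disjoint halves (without replacement);
    the first half is the reference.  Extra keyword arguments are
    passed to the metric (``m``/``task_dof`` for the PCA metric,
    ``G``/``noise_range``/``unwrap`` for the CRP metric).
    """
    if metric not in ("jcvpca", "jsvcrp"):
        raise ValueError(f"unknown metric {metric!r}")
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    k = len(ds)
    if k < 2:
        raise ValueError("need at least 2 repetitions to split")
    rng = np.random.default_rng(seed)
    values = []
    labels: list = []
    for _ in range(n_splits):
        ia, ib = _split_indices(k, rng)
        half_a = ds.subset(ia, name=f"{ds.name}/refhalf")
        half_b = ds.subset(ib, name=f"{ds.name}/cmphalf")
        if metric == "jcvpca":
            res = jcvpca(half_a, half_b, **metric_kwargs)
            values.append(res.delta)
            labels = [
                (f"PC{u + 1}", j)
                for u in range(res.delta.shape[0])
                for j in res.joint_names
            ]
        else:
            res = jsvcrp_all_pairs(half_a, half_b, **metric_kwargs)
            labels = list(res.areas.keys())
            values.append(np.array([res.areas[p] for p in labels]))
    samples = np.stack(values)
    mean = samples.mean(axis=0)
    sd = samples.std(axis=0, ddof=1) if n_splits > 1 else np.zeros_like(mean)
    return VariabilityThreshold(
        metric=metric,
        mean=mean,
        sd=sd,
        se=sd / np.sqrt(n_splits),
        entry_labels=labels,
        n_splits=n_splits,
        seed=seed,
        samples=samples.reshape(n_splits, -1),
    )


def exceeds_threshold(
    value: np.ndarray | float,
    threshold: VariabilityThreshold,
    rule: str = "se",
) -> np.ndarray:
    """Flag, per entry, whether an observed metric value lies outside
    the natural-variability interval mean +/- SE (default) or
    mean +/- SD (``rule='sd'``); values on the boundary are inside."""
    if rule not in ("se", "sd"):
        raise ValueError("rule must be 'se' or 'sd'")
    band = threshold.se if rule == "se" else threshold.sd
    value = np.asarray(value, dtype=float)
    if value.shape != threshold.mean.shape:
        raise ValueError(
            f"value shape {value.shape} does not match threshold shape "
            f"{threshold.mean.shape}"
        )
    return np.abs(value - threshold.mean) > band
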