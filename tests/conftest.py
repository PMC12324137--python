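import numpy as np
import pytest

from jointcoord import ArmSpec, Dataset, MovementRepetition, SineSpec
from jointcoord import make_reaching_dataset, make_sine_datasets


def make_dataset(angles_per_rep, joint_names, dt=0.01, name="ds", unit="rad"):
    """Build a dataset from a list of (T x n) angle arrays."""
    reps = []
    for ang in angles_per_rep:
        ang = np.asarray(ang, float)
        t = np.arange(ang.shape[0]) * dt
        reps.append(MovementRepetition(t, ang, list(joint_names)))
    return Dataset(name=name, repetitions=reps, joint_names=list(joint_names),
                   angle_unit=unit)


def random_dataset(rng, n_joints=2, n_reps=3, T=200, name="rand"):
    """Smooth random multi-joint dataset (band-limited noise)."""
    reps = []
    for _ in range(n_reps):
        raw = rng.normal(size=(T + 20, n_joints))
        kernel = np.hanning(21)
        smooth = np.column_stack(
            [np.convolve(raw[:, j], kernel, mode="valid") for j in range(n_joints)]
        )
        reps.append(smooth[:T] * rng.uniform(0.5, 2.0, size=n_joints))
    return make_dataset(reps, [f"j{i}" for i in range(n_joints)], name=name)


@pytest.fixture(scope="session")
def sine_pair():
    """The noise-free two-sine validation pair (A, B)."""
    return make_sine_datasets(SineSpec(noise_sd=0.0))


@pytest.fixture(scope="session")
def reaching_conditions():
    """All four simulated reaching conditions plus a second physiological
    run with a fresh seed (the within-condition baseline)."""
    conds = {
        s: make_reaching_dataset(ArmSpec(strategy=s, seed=10 + i))
        for i, s in enumerate(
            ("physiological", "desync", "shoulder_only", "elbow_overuse")
        )
    }
    conds["physiological2"] = make_reaching_dataset(
        ArmSpec(strategy="physiological", seed=99)
    )
    return conds


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
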