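"""Multi-repetition joint-angle datasets and their CSV layouts.

A movement study produces several repetitions of the same task, each a
table of joint angles against time.  Repetitions may differ in duration
but share the joint list and angle unit.  Two on-disk layouts are
supported:

* ``generic`` — a single CSV, or a flat folder of CSVs, with a leading
  ``time_s`` column followed by one column per joint.
* ``s4`` — one folder per experimental condition, each file named
  ``<target>_<rep>.csv`` (the layout of exoskeleton reaching recordings:
  repetitions of the movement toward each of several target heights,
  one CSV per repetition).

All numeric handling is unit-agnostic; the angle unit (``deg`` or
``rad``) is declared on load and carried through so that downstream
metrics can report in the recording's own unit.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MovementRepetition",
    "Dataset",
    "load_dataset",
    "write_dataset",
    "center_dataset",
    "SchemaError",
]

TIME_COLUMN = "time_s"

_ANGLE_UNITS = ("deg", "rad")


class SchemaError(ValueError):
    """A CSV file does not match the expected dataset schema."""


@dataclass
class MovementRepetition:
    """One recorded or simulated repetition of a movement task.

    Parameters
    ----------
    time:
        Strictly increasing sample times in seconds, length ``T``, or
        ``None`` when only time-agnostic analyses (PCA) are intended.
    angles:
        ``T x n`` array of joint angles, one column per joint.
    joint_names:
        Ordered labels of the ``n`` joints.
    meta:
        Free-form tags (condition, target, repetition index, ...).
    """

    time: np.ndarray | None
    angles: np.ndarray
    joint_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2:
            raise ValueError("angles must be a 2-D array (samples x joints)")
        if self.angles.shape[0] < 2:
            raise ValueError("a repetition needs at least 2 samples")
        if self.angles.shape[1] != len(self.joint_names):
            raise ValueError(
                f"angles has {self.angles.shape[1]} columns but "
                f"{len(self.joint_names)} joint names were given"
            )
        if np.isnan(self.angles).any():
            raise ValueError("angles contain missing values")
        if self.time is not None:
            self.time = np.asarray(self.time, dtype=float)
            if self.time.shape != (self.angles.shape[0],):
                raise ValueError("time vector length must match angle rows")
            if np.any(np.diff(self.time) <= 0):
                raise ValueError("time must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.angles.shape[0]

    @property
    def n_joints(self) -> int:
        return self.angles.shape[1]

    def joint(self, name: str) -> np.ndarray:
        """Return the angle trajectory of one joint by name."""
        return self.angles[:, self.joint_names.index(name)]


@dataclass
class Dataset:
    """Named collection of repetitions sharing a joint list and unit."""

    name: str
    repetitions: list[MovementRepetition]
    joint_names: list[str]
    angle_unit: str = "deg"
    centered: bool = False

    def __post_init__(self) -> None:
        if self.angle_unit not in _ANGLE_UNITS:
            raise ValueError(f"angle_unit must be one of {_ANGLE_UNITS}")
        if not self.repetitions:
            raise ValueError("a dataset needs at least one repetition")
        for rep in self.repetitions:
            if rep.joint_names != self.joint_names:
                raise SchemaError(
                    f"repetition joints {rep.joint_names} do not match "
                    f"dataset joints {self.joint_names}"
                )

    def __len__(self) -> int:
        return len(self.repetitions)

    def __iter__(self) -> Iterator[MovementRepetition]:
        return iter(self.repetitions)

    @property
    def n_joints(self) -> int:
        return len(self.joint_names)

    def stacked(self) -> np.ndarray:
        """All repetitions concatenated into one (sum T_r) x n sample matrix."""
        return np.vstack([rep.angles for rep in self.repetitions])

    def subset(self, indices: Sequence[int], name: str | None = None) -> "Dataset":
        """New dataset keeping only the repetitions at ``indices``."""
        return replace(
            self,
            name=name or self.name,
            repetitions=[self.repetitions[i] for i in indices],
        )


def _read_repetition_csv(path: Path, require_time: bool) -> tuple[pd.DataFrame, list[str]]:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: need a time column plus at least one joint column")
    n_dropped = int(df.isna().any(axis=1).sum())
    if n_dropped:
        df = df.dropna(axis=0)
    if len(df) < 2:
        raise SchemaError(f"{path}: fewer than 2 complete rows")
    cols = list(df.columns)
    time_like = {"time_s", "time", "t", "timestamp"}
    if TIME_COLUMN in cols:
        time_col = TIME_COLUMN
    elif cols[0].strip().lower() in time_like:
        time_col = cols[0]
    elif require_time:
        raise SchemaError(f"{path}: no recognizable time column")
    else:
        time_col = None
    joint_cols = [c for c in cols if c != time_col]
    df.attrs["n_dropped_rows"] = n_dropped
    df.attrs["time_col"] = time_col
    return df, joint_cols


def _repetition_from_frame(df: pd.DataFrame, joint_cols: list[str], meta: dict) -> MovementRepetition:
    time_col = df.attrs.get("time_col")
    time = df[time_col].to_numpy(float) if time_col else None
    meta = dict(meta)
    if df.attrs.get("n_dropped_rows"):
        meta["dropped_rows"] = df.attrs["n_dropped_rows"]
    try:
        return MovementRepetition(time, df[joint_cols].to_numpy(float), list(joint_cols), meta)
    except ValueError as exc:
        raise SchemaError(f"{meta.get('source', '<csv>')}: {exc}") from exc


_S4_NAME = re.compile(r"^(?P<target>.+)_(?P<rep>\d+)\.csv$")


def _parse_s4_meta(path: Path) -> dict:
    meta = {"source": str(path), "condition": path.parent.name}
    m = _S4_NAME.match(path.name)
    if m:
        meta["target"] = m.group("target")
        meta["repetition"] = int(m.group("rep"))
    return meta


def load_dataset(
    root_path: str | Path,
    layout: str = "auto",
    angle_unit: str | None = None,
    name: str | None = None,
) -> Dataset:
    """Load a dataset from a CSV file or a folder of CSVs.

    ``layout='s4'`` expects a condition folder of ``<target>_<rep>.csv``
    files; ``layout='generic'`` a file or flat folder with a ``time_s``
    column; ``'auto'`` guesses from the path.  Joint columns are taken
    from the first file (sorted order) and enforced on the rest.  Rows
    with missing cells are rejected (dropped), never imputed.
    """
    root = Path(root_path)
    if not root.exists():
        raise FileNotFoundError(root)
    if layout not in ("auto", "s4", "generic"):
        raise ValueError(f"unknown layout {layout!r}")

    sidecar_meta: dict = {}
    if root.is_file():
        files = [root]
    else:
        sidecar = root / "dataset.json"
        if sidecar.exists():
            sidecar_meta = json.loads(sidecar.read_text())
        files = sorted(p for p in root.glob("*.csv"))
        if not files:
            raise FileNotFoundError(f"no CSV files in {root}")
    if layout == "auto":
        layout = "s4" if (root.is_dir() and all(_S4_NAME.match(p.name) for p in files)) else "generic"

    if angle_unit is None:
        angle_unit = sidecar_meta.get("angle_unit", "deg")

    reps: list[MovementRepetition] = []
    ref_joints: list[str] | None = sidecar_meta.get("joint_names")
    for path in files:
        df, joint_cols = _read_repetition_csv(path, require_time=False)
        if ref_joints is None:
            ref_joints = joint_cols
        elif joint_cols != ref_joints:
            raise SchemaError(
                f"{path}: joint columns {joint_cols} do not match {ref_joints} "
                f"from the first file"
            )
        meta = _parse_s4_meta(path) if layout == "s4" else {"source": str(path)}
        reps.append(_repetition_from_frame(df, joint_cols, meta))

    ds_name = name or sidecar_meta.get("name") or (root.stem if root.is_file() else root.name)
    return Dataset(
        name=ds_name,
        repetitions=reps,
        joint_names=list(ref_joints),
        angle_unit=angle_unit,
        centered=bool(sidecar_meta.get("centered", False)),
    )


def write_dataset(ds: Dataset, root_path: str | Path) -> Path:
    """Write one CSV per repetition plus a ``dataset.json`` sidecar.

    Files are named ``<target>_<rep>.csv`` when the repetition meta
    carries those tags (mirroring the condition-folder layout) and
    ``rep_<i>.csv`` otherwise.  ``load_dataset`` round-trips the result.
    """
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)
    for i, rep in enumerate(ds.repetitions):
        if "target" in rep.meta and "repetition" in rep.meta:
            fname = f"{rep.meta['target']}_{rep.meta['repetition']}.csv"
        else:
            fname = f"rep_{i:03d}.csv"
        cols: dict[str, np.ndarray] = {}
        if rep.time is not None:
            cols[TIME_COLUMN] = rep.time
        for j, jn in enumerate(ds.joint_names):
            cols[jn] = rep.angles[:, j]
        pd.DataFrame(cols).to_csv(root / fname, index=False, float_format="%.12g")
    sidecar = {
        "name": ds.name,
        "angle_unit": ds.angle_unit,
        "joint_names": ds.joint_names,
        "centered": ds.centered,
        "n_repetitions": len(ds),
    }
    (root / "dataset.json").write_text(json.dumps(sidecar, indent=2))
    return root


def center_dataset(ds: Dataset) -> Dataset:
    """Subtract each joint's grand mean over all repetitions pooled.

    Centering uses the mean of the concatenated samples of the whole
    dataset (not per-repetition means), because the reference PCA is
    computed on that same concatenation.  Amplitudes are deliberately
    not rescaled, so joints that move more keep their larger variance.
    Centering removes constant offsets in the starting position and is
    idempotent.
    """
    grand_mean = ds.stacked().mean(axis=0)
    reps = [
        replace(rep, angles=rep.angles - grand_mean, meta=dict(rep.meta))
        for rep in ds.repetitions
    ]
    return replace(ds, repetitions=reps, centered=True)
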