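"""JcvPCA: joint-contribution variation via PCA reprojection.

The metric compares the spatial structure of two movement datasets
that share a joint list.  Its four steps:

1. PCA on a *reference* dataset A of centered joint-angle samples,
   giving an orthonormal frame ``R_A`` whose rows are principal
   components — linear combinations of the joints ordered by the
   movement variance they capture.
2. Every sample of the comparison dataset B is projected into ``R_A``.
3. A second PCA on the projected samples; composing its eigenvectors
   with ``R_A`` expresses each comparison PC directly in the reference
   joint space.  The element-wise absolute values of both weight
   matrices are the Joint Reprojection Weights (JRW).
4. Per joint and per PC, the reference weight is subtracted from the
   reprojected comparison weight.  A positive entry means the joint
   contributes *more* in the comparison dataset, a negative entry less;
   all entries lie in ``[-1, 1]``.

The comparison is intentionally asymmetric: swapping reference and
comparison datasets answers a different question, so the reference
must be chosen deliberately (typically a baseline condition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import Dataset, MovementRepetition, center_dataset

__all__ = [
    "PCAFrame",
    "JRW",
    "JcvPCAResult",
    "fit_pca",
    "reproject",
    "joint_reprojection_weights",
    "jcvpca",
    "bootstrap_stability",
]


@dataclass
class PCAFrame:
    """PCA of a centered dataset: the reference frame ``R_A``.

    ``eigvecs`` is ``m x n``; row ``u`` holds the coefficients of the
    ``u``-th principal component over the ``n`` input variables.  Rows
    are orthonormal, ordered by decreasing eigenvalue, and sign-fixed
    so the largest-magnitude coefficient of each row is positive.
    """

    eigvecs: np.ndarray
    eigvals: np.ndarray
    evr: np.ndarray
    joint_means: np.ndarray
    variable_names: list[str]

    @property
    def m(self) -> int:
        return self.eigvecs.shape[0]

    @property
    def n(self) -> int:
        return self.eigvecs.shape[1]

    def component_labels(self) -> list[str]:
        return [f"PC{u + 1}" for u in range(self.m)]


@dataclass
class JRW:
    """Joint Reprojection Weights: |weights| of both datasets' PCs
    expressed in the reference joint space, with explained-variance
    ratios of both frames."""

    ref_weights: np.ndarray  # m x n, |a_{u,i}|
    cmp_weights: np.ndarray  # m x n, |b^A_{u,i}|
    signed_cmp: np.ndarray   # m x n, b^A_{u,i} before the absolute value
    evr_ref: np.ndarray
    evr_cmp: np.ndarray
    joint_names: list[str]


@dataclass
class JcvPCAResult:
    """Per-joint, per-PC contribution change of the comparison dataset
    relative to the reference; entries in ``[-1, 1]``."""

    delta: np.ndarray                   # m x n
    weighted_delta: np.ndarray | None   # m x n, delta scaled by reference EVR
    jrw: JRW
    joint_names: list[str]

    @property
    def m(self) -> int:
        return self.delta.shape[0]

    def to_frame(self, weighted: bool = False) -> pd.DataFrame:
        """Delta matrix as a labelled DataFrame (PCs x joints)."""
        mat = self.weighted_delta if weighted else self.delta
        if mat is None:
            raise ValueError("result was computed without EVR weighting")
        idx = [f"PC{u + 1}" for u in range(self.m)]
        return pd.DataFrame(mat, index=idx, columns=self.joint_names)

    def to_dict(self) -> dict:
        out = {
            "joint_names": self.joint_names,
            "delta": self.delta.tolist(),
            "jrw_ref": self.jrw.ref_weights.tolist(),
            "jrw_cmp": self.jrw.cmp_weights.tolist(),
            "evr_ref": self.jrw.evr_ref.tolist(),
            "evr_cmp": self.jrw.evr_cmp.tolist(),
        }
        if self.weighted_delta is not None:
            out["weighted_delta"] = self.weighted_delta.tolist()
        return out


def _fix_signs(eigvecs: np.ndarray) -> np.ndarray:
    """Flip each eigenvector so its largest-|coefficient| is positive.

    PCA eigenvectors are defined up to sign; this deterministic
    convention is irrelevant once absolute values are taken but makes
    frames comparable across runs and self-projection tests exact.
    """
    out = eigvecs.copy()
    for u in range(out.shape[0]):
        if out[u, np.argmax(np.abs(out[u]))] < 0:
            out[u] = -out[u]
    return out


def fit_pca(ds: Dataset, m: int | None = None) -> PCAFrame:
    """PCA of the concatenated samples of a centered dataset.

    Computed by singular value decomposition of the stacked sample
    matrix (numerically safer than forming the covariance explicitly);
    eigenvalues are sample variances with ``1/(N-1)`` normalization.
    Retains the leading ``m`` components (default: all ``n``).

    Emits a warning when the total sample count is below five samples
    per variable, the usual lower bound of the variable-to-factor
    guidance for trustworthy PCA.
    """
    if not ds.centered:
        raise ValueError("fit_pca expects a centered dataset; use center_dataset first")
    n = ds.n_joints
    if m is None:
        m = n
    if not 1 <= m <= n:
        raise ValueError(f"m={m} must be in 1..{n}")
    X = ds.stacked()
    N = X.shape[0]
    if N < 5 * n:
        warnings.warn(
            f"only {N} samples for {n} variables (< 5 per variable); "
            "the PCA may be unstable",
            UserWarning,
            stacklevel=2,
        )
    # means are ~0 after centering; keep the residual for bookkeeping
    means = X.mean(axis=0)
    _, s, vt = np.linalg.svd(X - means, full_matrices=False)
    eigvals_all = s**2 / (N - 1)
    total = eigvals_all.sum()
    evr_all = eigvals_all / total if total > 0 else np.zeros_like(eigvals_all)
    return PCAFrame(
        eigvecs=_fix_signs(vt[:m]),
        eigvals=eigvals_all[:m],
        evr=evr_all[:m],
        joint_means=means,
        variable_names=list(ds.joint_names),
    )


def reproject(cmp: Dataset, frame: PCAFrame) -> Dataset:
    """Express every sample of ``cmp`` in the coordinates of ``frame``.

    The joint list of ``cmp`` must match the frame's variables exactly
    (same names, same order); nothing is reordered silently.  The
    output carries PC labels instead of joint labels.  Because the
    frame rows are orthonormal, total variance is preserved when the
    frame retains all components.
    """
    if cmp.joint_names != frame.variable_names:
        raise ValueError(
            f"joint mismatch: dataset has {cmp.joint_names}, "
            f"frame was fit on {frame.variable_names}"
        )
    labels = frame.component_labels()
    reps = [
        MovementRepetition(
            rep.time, rep.angles @ frame.eigvecs.T, list(labels), dict(rep.meta)
        )
        for rep in cmp.repetitions
    ]
    return Dataset(
        name=f"{cmp.name}@{'.'.join(frame.variable_names)}",
        repetitions=reps,
        joint_names=list(labels),
        angle_unit=cmp.angle_unit,
        centered=cmp.centered,
    )


def joint_reprojection_weights(frame_ref: PCAFrame, frame_cmp_projected: PCAFrame) -> JRW:
    """Compose the comparison PCA (over PC coordinates) with the
    reference frame to express comparison PCs in the reference joint
    space, and take element-wise absolute values of both weight
    matrices.

    Both underlying signed matrices have orthonormal rows, so each
    weight row has unit Euclidean norm and all entries lie in [0, 1].
    """
    if frame_cmp_projected.n != frame_ref.m:
        raise ValueError(
            f"comparison frame spans {frame_cmp_projected.n} coordinates but "
            f"the reference frame provides {frame_ref.m} components"
        )
    signed_cmp = frame_cmp_projected.eigvecs @ frame_ref.eigvecs
    return JRW(
        ref_weights=np.abs(frame_ref.eigvecs),
        cmp_weights=np.abs(signed_cmp),
        signed_cmp=signed_cmp,
        evr_ref=frame_ref.evr.copy(),
        evr_cmp=frame_cmp_projected.evr.copy(),
        joint_names=list(frame_ref.variable_names),
    )


def jcvpca(
    ref: Dataset,
    cmp: Dataset,
    m: int | None = None,
    task_dof: int | None = None,
    weight_by_evr: bool = False,
    center: bool = True,
) -> JcvPCAResult:
    """Joint-contribution change of ``cmp`` relative to reference ``ref``.

    Parameters
    ----------
    m:
        Number of principal components to retain.  Defaults to
        ``task_dof + 1`` when the task's degree-of-freedom count is
        given (one component beyond the task span captures the most
        informative part of the null space), otherwise to the number
        of joints.
    weight_by_evr:
        Additionally return the delta matrix scaled row-wise by the
        reference frame's explained-variance ratios, so rows can be
        summed into a single change score while staying in [-1, 1].
    center:
        Center each dataset on its own grand mean first (skipped for
        datasets already flagged centered).

    Notes
    -----
    The sign convention is *positive = joint more used in the
    comparison dataset*.  Equal datasets give an exactly zero matrix.
    """
    if ref.joint_names != cmp.joint_names:
        raise ValueError("reference and comparison datasets must share joints")
    if m is None and task_dof is not None:
        m = task_dof + 1
    if center:
        if not ref.centered:
            ref = center_dataset(ref)
        if not cmp.centered:
            cmp = center_dataset(cmp)
    frame_ref = fit_pca(ref, m)
    projected = reproject(cmp, frame_ref)
    frame_cmp = fit_pca(projected, frame_ref.m)
    jrw = joint_reprojection_weights(frame_ref, frame_cmp)
    delta = jrw.cmp_weights - jrw.ref_weights
    weighted = jrw.evr_ref[:, None] * delta if weight_by_evr else None
    return JcvPCAResult(
        delta=delta,
        weighted_delta=weighted,
        jrw=jrw,
        joint_names=list(ref.joint_names),
    )


def bootstrap_stability(
    ds: Dataset,
    m: int | None = None,
    n_boot: int = 50,
    seed: int | None = None,
) -> float:
    """Stability check of the reference PCA: resample repetitions with
    replacement, refit, and report the maximum row-wise deviation
    ``max_u (1 - |v_u . v*_u|)`` between original and bootstrap
    eigenvectors (0 = perfectly stable, 1 = orthogonal).

    Large values signal that the dataset is too small for the frame to
    be trusted.
    """
    if not ds.centered:
        ds = center_dataset(ds)
    base = fit_pca(ds, m)
    rng = np.random.default_rng(seed)
    k = len(ds)
    worst = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for _ in range(n_boot):
            idx = rng.integers(0, k, size=k)
            boot = fit_pca(center_dataset(ds.subset(idx, name=f"{ds.name}*")), m)
            align = np.abs(np.sum(base.eigvecs * boot.eigvecs, axis=1))
            worst = max(worst, float(np.max(1.0 - align)))
    return worst
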