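"""Diffusion tensor fitting, scalar maps, and head-motion quality control.

The diffusion tensor D is fit per voxel from the monoexponential signal model
S(g) = S0 * exp(-b * g' D g) by ordinary least squares on the log signal.  The
sorted eigenvalues l1 >= l2 >= l3 of D give the scalar maps:

    AD = l1,  RD = (l2 + l3)/2,  MD = (l1 + l2 + l3)/3,
    FA = sqrt(3/2) * ||l - mean(l)|| / ||l||.

Head motion QC converts the three rotation parameters (radians) to arc
displacement at a 50 mm head radius and excludes a subject when any converted
rotation or any translation strictly exceeds 1.5 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiffusionVolume",
    "TensorMaps",
    "MotionTrace",
    "QCResult",
    "fit_tensor",
    "fa_from_eigenvalues",
    "motion_qc",
    "compute_tiv",
]

_EVAL_FLOOR = 1e-12  # clamp for negative eigenvalues from noisy fits


@dataclass
class DiffusionVolume:
    """4D diffusion-weighted signal with its gradient table.

    signal: (x, y, z, n_volumes) array, arbitrary units.
    bvecs: (n_volumes, 3) unit gradient directions (ignored for b=0).
    bvals: (n_volumes,) diffusion weightings, s/mm^2.  Exactly one b=0 volume.
    voxel_size: (3,) voxel dimensions in mm.
    brain_mask: boolean (x, y, z); defaults to everything.
    """

    signal: np.ndarray
    bvecs: np.ndarray
    bvals: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 2.0)
    brain_mask: np.ndarray | None = None

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, volume)")
        n_vol = self.signal.shape[3]
        if self.bvecs.shape != (n_vol, 3):
            raise ValueError("bvecs must have shape (n_volumes, 3)")
        if self.bvals.shape != (n_vol,):
            raise ValueError("bvals must have one entry per volume")
        n_b0 = int(np.sum(self.bvals == 0))
        if n_b0 != 1:
            raise ValueError(f"exactly one b=0 volume required, found {n_b0}")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("diffusion-weighted bvecs must be unit vectors")
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.signal.shape[:3], dtype=bool)
        else:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.signal.shape[:3]:
                raise ValueError("brain_mask shape must match the signal grid")

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[3]


@dataclass
class TensorMaps:
    """Per-voxel tensor eigensystem and derived scalar maps."""

    eigenvalues: np.ndarray  # (x, y, z, 3) sorted descending, mm^2/s
    eigenvectors: np.ndarray  # (x, y, z, 3, 3) columns matched to eigenvalues
    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    mask: np.ndarray  # voxels with a valid fit
    tensor: np.ndarray | None = None  # (x, y, z, 3, 3) full tensor
    clamped: np.ndarray | None = None  # voxels whose eigenvalues were floored
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 2.0)

    @property
    def v1(self) -> np.ndarray:
        """Principal eigenvector field, (x, y, z, 3)."""
        return self.eigenvectors[..., :, 0]


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion: 3 translations (mm) and 3 rotations (radians)."""

    translations: np.ndarray  # (n_volumes, 3) mm
    rotations: np.ndarray  # (n_volumes, 3) radians

    def __post_init__(self):
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        if self.translations.shape != self.rotations.shape or self.translations.shape[1] != 3:
            raise ValueError("translations and rotations must both be (n_volumes, 3)")
        if not (np.isfinite(self.translations).all() and np.isfinite(self.rotations).all()):
            raise ValueError("motion parameters must be finite")

    @property
    def n_volumes(self) -> int:
        return self.translations.shape[0]


@dataclass
class QCResult:
    retain: bool
    max_translation_mm: float
    max_rotation_mm: float  # arc displacement at the reference radius

    @property
    def decision(self) -> str:
        return "retain" if self.retain else "exclude"


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from eigenvalue triples (last axis length 3)."""
    evals = np.asarray(evals, dtype=float)
    mean = evals.mean(axis=-1, keepdims=True)
    num = np.sqrt(((evals - mean) ** 2).sum(axis=-1))
    den = np.sqrt((evals**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows map [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] to ln S."""
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    b = bvals
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx * gx,
            -b * gy * gy,
            -b * gz * gz,
            -2 * b * gx * gy,
            -2 * b * gx * gz,
            -2 * b * gy * gz,
        ]
    )


def fit_tensor(volume: DiffusionVolume) -> TensorMaps:
    """Ordinary least-squares log-linear tensor fit per masked voxel.

    Voxels with any non-positive signal are flagged and excluded from the output
    maps.  Raises if the gradient scheme cannot determine the six tensor
    components (rank-deficient design).
    """
    if volume.n_volumes < 7:
        raise ValueError("tensor fit requires >= 7 volumes (1 b=0 + 6 directions)")
    design = _design_matrix(volume.bvals, volume.bvecs)
    if np.linalg.matrix_rank(design) < 7:
        raise ValueError("rank-deficient gradient scheme: cannot fit 6 tensor components")

    shape = volume.signal.shape[:3]
    mask = volume.brain_mask.copy()
    sig = volume.signal[mask]  # (n_vox, n_volumes)
    positive = (sig > 0).all(axis=1)
    if not positive.all():
        bad = np.zeros(mask.sum(), dtype=bool)
        bad[~positive] = True
        idx = np.argwhere(mask)
        for i, j, k in idx[bad]:
            mask[i, j, k] = False
        sig = sig[positive]

    pinv = np.linalg.pinv(design)
    coef = np.log(sig) @ pinv.T  # (n_vox, 7), columns per _design_matrix ordering
    dxx, dyy, dzz, dxy, dxz, dyz = (coef[:, i] for i in range(1, 7))

    n_vox = coef.shape[0]
    tensors = np.empty((n_vox, 3, 3))
    tensors[:, 0, 0] = dxx
    tensors[:, 1, 1] = dyy
    tensors[:, 2, 2] = dzz
    tensors[:, 0, 1] = tensors[:, 1, 0] = dxy
    tensors[:, 0, 2] = tensors[:, 2, 0] = dxz
    tensors[:, 1, 2] = tensors[:, 2, 1] = dyz

    evals, evecs = np.linalg.eigh(tensors)  # ascending
    evals = evals[:, ::-1]
    evecs = evecs[:, :, ::-1]
    clamped_flat = (evals <= 0).any(axis=1)
    evals = np.maximum(evals, _EVAL_FLOOR)

    full = lambda fill=0.0: np.full(shape, fill)  # noqa: E731
    maps = TensorMaps(
        eigenvalues=np.zeros(shape + (3,)),
        eigenvectors=np.zeros(shape + (3, 3)),
        fa=full(),
        md=full(),
        ad=full(),
        rd=full(),
        mask=mask,
        tensor=np.zeros(shape + (3, 3)),
        clamped=np.zeros(shape, dtype=bool),
        voxel_size=volume.voxel_size,
    )
    maps.eigenvalues[mask] = evals
    maps.eigenvectors[mask] = evecs
    maps.tensor[mask] = tensors
    maps.clamped[mask] = clamped_flat
    maps.fa[mask] = fa_from_eigenvalues(evals)
    maps.md[mask] = evals.mean(axis=1)
    maps.ad[mask] = evals[:, 0]
    maps.rd[mask] = (evals[:, 1] + evals[:, 2]) / 2
    return maps


def motion_qc(
    trace: MotionTrace, limit: float = 1.5, radius: float = 50.0
) -> QCResult:
    """Retain/exclude decision from head-motion parameters.

    Rotations (radians) are converted to arc displacement theta * radius (mm)
    and compared, like the translations, against `limit` in mm; exclusion
    requires a strict exceedance.
    """
    if trace.n_volumes == 0:
        raise ValueError("empty motion trace")
    max_trans = float(np.abs(trace.translations).max())
    max_rot = float(np.abs(trace.rotations).max() * radius)
    retain = not (max_trans > limit or max_rot > limit)
    return QCResult(retain=retain, max_translation_mm=max_trans, max_rotation_mm=max_rot)


def compute_tiv(gm_volume: float, wm_volume: float) -> float:
    """Total intracranial volume as the sum of grey- and white-matter volume (mm^3)."""
    if gm_volume < 0 or wm_volume < 0:
        raise ValueError("tissue volumes must be nonnegative")
    return float(gm_volume + wm_volume)
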