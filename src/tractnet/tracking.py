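"""Deterministic streamline tractography and connectome construction.

Streamlines are traced by Euler integration along the principal eigenvector
field of the fitted tensors, in millimetre space, with a fixed 0.5 mm step.
Tracking starts at the centre of every white-matter voxel with FA >= 0.2 and
runs in both antipodal directions; a streamline stops when it enters a voxel
below the FA floor, when the turning angle between successive steps exceeds
60 degrees, when it leaves the tracking mask, or at a step-count safety cap.

The connectome records, for every pair of atlas ROIs, how many streamlines
touch both regions, plus the mean axial diffusivity sampled over all voxels
visited by the connecting streamlines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .tensor import TensorMaps

__all__ = [
    "ROIAtlas",
    "Streamline",
    "ConnectivityMatrix",
    "track_streamline",
    "run_whole_brain",
    "build_connectome",
]

MAX_STEPS = 2000  # safety cap guaranteeing termination


@dataclass
class ROIAtlas:
    """Integer-labelled ROI volume (0 = background) with a label table."""

    labels: np.ndarray  # 3D integer volume
    table: dict[int, tuple[str, str, str]]  # label -> (name, hemisphere, system)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 2.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas label volume must be 3D")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.table)
        if missing:
            raise ValueError(f"labels present in volume but absent from table: {missing}")

    @property
    def n_labels(self) -> int:
        return len(self.table)

    @property
    def node_names(self) -> list[str]:
        return [
            f"{hemi}_{name}" for _, (name, hemi, _sys) in sorted(self.table.items())
        ]


@dataclass
class Streamline:
    """Polyline in mm, its seed voxel, and the termination reason of each branch."""

    points: np.ndarray  # (n_points, 3) mm
    seed: tuple[int, int, int]
    reasons: tuple[str, str]  # (backward branch, forward branch)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("streamline needs >= 2 points of shape (n, 3)")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ConnectivityMatrix:
    """Symmetric streamline-count matrix with parallel mean-AD edge weights."""

    counts: np.ndarray  # (n, n) nonnegative integers, zero diagonal
    mean_ad: np.ndarray  # (n, n) mm^2/s, zero where counts == 0
    node_names: list[str] | None = None
    subject: str | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.mean_ad = np.asarray(self.mean_ad, dtype=float)
        if self.counts.shape != self.mean_ad.shape:
            raise ValueError("counts and mean_ad must share a shape")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if np.diag(self.counts).any():
            raise ValueError("counts must have a zero diagonal")
        if (self.counts < 0).any() or (self.mean_ad < 0).any():
            raise ValueError("counts and mean_ad must be nonnegative")
        if ((self.mean_ad > 0) != (self.counts > 0)).any():
            raise ValueError("mean_ad must be positive exactly where counts > 0")

    @property
    def n_nodes(self) -> int:
        return self.counts.shape[0]


def _trilinear_tensor(field: np.ndarray, pos_idx: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a (x, y, z, 3, 3) tensor field at a float index."""
    shape = np.array(field.shape[:3])
    p = np.clip(pos_idx, 0.0, shape - 1.0)
    i0 = np.floor(p).astype(int)
    i0 = np.minimum(i0, shape - 2)
    i0 = np.maximum(i0, 0)
    f = p - i0
    out = np.zeros((3, 3))
    for dx in (0, 1):
        wx = f[0] if dx else 1.0 - f[0]
        for dy in (0, 1):
            wy = f[1] if dy else 1.0 - f[1]
            for dz in (0, 1):
                wz = f[2] if dz else 1.0 - f[2]
                w = wx * wy * wz
                if w > 0:
                    out += w * field[i0[0] + dx, i0[1] + dy, i0[2] + dz]
    return out


def _principal_direction(tensor_field: np.ndarray, pos_idx: np.ndarray) -> np.ndarray:
    d = _trilinear_tensor(tensor_field, pos_idx)
    _evals, evecs = np.linalg.eigh(d)
    return evecs[:, 2]  # largest eigenvalue last in eigh ordering


def _sample_vmf(mu: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """von Mises-Fisher sample on S^2 around mu (closed form for dimension 3)."""
    if kappa <= 0:
        return mu
    u = rng.uniform()
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    # random unit vector perpendicular to mu
    v = rng.standard_normal(3)
    v -= v.dot(mu) * mu
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        return mu
    v /= norm
    return w * mu + np.sqrt(max(0.0, 1.0 - w * w)) * v


def _nearest_voxel(pos_mm: np.ndarray, voxel_size: np.ndarray) -> np.ndarray:
    # floor(x + 0.5): nearest voxel with ties toward +, independent of parity
    return np.floor(pos_mm / voxel_size + 0.5).astype(int)


def track_streamline(
    seed: tuple[int, int, int],
    tensors: TensorMaps,
    wm_fa_mask: np.ndarray,
    step: float = 0.5,
    fa_floor: float = 0.2,
    max_angle: float = 60.0,
    direction_jitter: float = 0.0,
    rng: np.random.Generator | None = None,
    max_steps: int = MAX_STEPS,
) -> Streamline:
    """Track one streamline bidirectionally from a seed voxel centre.

    `direction_jitter` is the von Mises-Fisher concentration kappa of an angular
    perturbation applied to the local principal direction (0 disables it),
    giving a desk-scale stand-in for probabilistic fibre-direction sampling.
    `max_angle` is in degrees.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    seed = tuple(int(s) for s in seed)
    mask = np.asarray(wm_fa_mask, dtype=bool)
    if not mask[seed]:
        raise ValueError(f"seed voxel {seed} is outside the tracking mask")
    if tensors.fa[seed] < fa_floor:
        raise ValueError(f"seed voxel {seed} has FA below the floor {fa_floor}")

    vs = np.asarray(tensors.voxel_size, dtype=float)
    shape = np.array(mask.shape)
    cos_limit = np.cos(np.deg2rad(max_angle))
    seed_mm = np.asarray(seed) * vs

    v0 = _principal_direction(tensors.tensor, seed_mm / vs)
    if direction_jitter > 0:
        v0 = _sample_vmf(v0, direction_jitter, rng)

    def _branch(direction: np.ndarray) -> tuple[list[np.ndarray], str]:
        pts: list[np.ndarray] = []
        pos = seed_mm.copy()
        prev = direction
        for step_i in range(max_steps):
            if step_i == 0:
                d = prev
            else:
                d = _principal_direction(tensors.tensor, pos / vs)
                if direction_jitter > 0:
                    d = _sample_vmf(d, direction_jitter, rng)
                if np.linalg.norm(d) < 1e-12:
                    return pts, "fa_floor"
                if d.dot(prev) < 0:
                    d = -d
                if d.dot(prev) < cos_limit:
                    return pts, "curvature"
            nxt = pos + step * d
            vox = _nearest_voxel(nxt, vs)
            if (vox < 0).any() or (vox >= shape).any() or not mask[tuple(vox)]:
                return pts, "left_mask"
            if tensors.fa[tuple(vox)] < fa_floor:
                return pts, "fa_floor"
            pts.append(nxt)
            pos = nxt
            prev = d
        return pts, "max_steps"

    fwd, reason_fwd = _branch(v0)
    bwd, reason_bwd = _branch(-v0)
    points = list(reversed(bwd)) + [seed_mm] + fwd
    if len(points) < 2:
        # degenerate seed surrounded by termination: keep a minimal 2-point line
        points = [seed_mm, seed_mm + step * v0]
    return Streamline(np.array(points), seed, (reason_bwd, reason_fwd))


def run_whole_brain(
    tensors: TensorMaps,
    wm_mask: np.ndarray,
    step: float = 0.5,
    fa_floor: float = 0.2,
    max_angle: float = 60.0,
    direction_jitter: float = 0.0,
    samples_per_seed: int = 1,
    seed: int = 0,
    max_steps: int = MAX_STEPS,
) -> list[Streamline]:
    """One (or `samples_per_seed`) tracking invocations per eligible WM voxel.

    Eligible seeds are WM voxels with FA >= fa_floor, visited in sorted voxel
    order so the result is deterministic for a fixed RNG seed.
    """
    mask = np.asarray(wm_mask, dtype=bool)
    eligible = np.argwhere(mask & (tensors.fa >= fa_floor))
    if len(eligible) == 0:
        warnings.warn("no eligible seed voxels (WM with FA above floor)", stacklevel=2)
        return []
    order = np.lexsort((eligible[:, 2], eligible[:, 1], eligible[:, 0]))
    rng = np.random.default_rng(seed)
    out = []
    for idx in eligible[order]:
        for _ in range(samples_per_seed):
            out.append(
                track_streamline(
                    tuple(idx),
                    tensors,
                    mask,
                    step=step,
                    fa_floor=fa_floor,
                    max_angle=max_angle,
                    direction_jitter=direction_jitter,
                    rng=rng,
                    max_steps=max_steps,
                )
            )
    return out


def build_connectome(
    streamlines: list[Streamline],
    atlas: ROIAtlas,
    ad_map: np.ndarray,
    subject: str | None = None,
) -> ConnectivityMatrix:
    """Streamline-count connectivity with mean-AD edge weights.

    A streamline connects ROI pair (i, j) when its point set intersects both
    label regions (nearest-voxel lookup); a streamline touching three or more
    ROIs increments every touched pair.  mean_ad(i, j) averages AD over all
    voxels visited by all (i, j)-connecting streamlines.
    """
    ad_map = np.asarray(ad_map, dtype=float)
    if atlas.labels.shape != ad_map.shape:
        raise ValueError(
            f"atlas grid {atlas.labels.shape} does not match AD map grid {ad_map.shape}"
        )
    n = atlas.n_labels
    vs = np.asarray(atlas.voxel_size, dtype=float)
    shape = np.array(atlas.labels.shape)
    counts = np.zeros((n, n), dtype=int)
    ad_sum = np.zeros((n, n))
    ad_n = np.zeros((n, n), dtype=int)

    for sl in streamlines:
        vox = np.floor(sl.points / vs + 0.5).astype(int)
        vox = np.clip(vox, 0, shape - 1)
        vox = np.unique(vox, axis=0)
        labels = np.unique(atlas.labels[vox[:, 0], vox[:, 1], vox[:, 2]])
        labels = labels[labels > 0]
        if len(labels) < 2:
            continue
        ad_total = ad_map[vox[:, 0], vox[:, 1], vox[:, 2]].sum()
        n_vox = len(vox)
        for a_i in range(len(labels)):
            for b_i in range(a_i + 1, len(labels)):
                i, j = labels[a_i] - 1, labels[b_i] - 1
                counts[i, j] += 1
                counts[j, i] += 1
                ad_sum[i, j] += ad_total
                ad_sum[j, i] += ad_total
                ad_n[i, j] += n_vox
                ad_n[j, i] += n_vox

    mean_ad = np.zeros((n, n))
    hit = ad_n > 0
    mean_ad[hit] = ad_sum[hit] / ad_n[hit]
    names = atlas.node_names if len(atlas.table) == n else None
    return ConnectivityMatrix(counts, mean_ad, node_names=names, subject=subject)
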