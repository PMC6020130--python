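"""Synthetic diffusion-weighted phantoms with known ground truth.

A phantom is a voxel grid holding isotropic background plus anisotropic fibre
bundles laid along polyline paths.  Every voxel's diffusion tensor D is known
exactly, so the monoexponential signal S(g) = S0 * exp(-b g' D g) can be
evaluated in closed form, optionally corrupted by Rician noise, and downstream
tensor fitting can be validated against the stored ground truth.

Bundle endpoints are labelled as ROI regions, which makes a phantom a complete
end-to-end fixture: signal -> tensor fit -> tracking -> connectome, with the
planted bundle topology as the expected answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rois import study_label_table
from .tensor import DiffusionVolume, MotionTrace, TensorMaps, fa_from_eigenvalues
from .tracking import ROIAtlas

__all__ = [
    "Bundle",
    "PhantomSpec",
    "make_phantom",
    "make_motion_trace",
    "gradient_scheme",
    "study_phantom_spec",
]

DEFAULT_EVALS = (1.5e-3, 0.4e-3, 0.4e-3)  # mm^2/s, FA ~ 0.72


@dataclass
class Bundle:
    """A fibre bundle: polyline path (mm), tube radius, eigenvalues, 1-based label."""

    path: np.ndarray  # (n_points, 3) mm
    radius: float = 1.5  # mm
    eigenvalues: tuple[float, float, float] = DEFAULT_EVALS
    label: int = 1

    def __post_init__(self):
        self.path = np.atleast_2d(np.asarray(self.path, dtype=float))
        if self.path.shape[1] != 3 or len(self.path) < 2:
            raise ValueError("bundle path needs >= 2 points of shape (n, 3)")
        l1, l2, l3 = self.eigenvalues
        if not (l1 >= l2 >= l3 > 0):
            raise ValueError("bundle eigenvalues must satisfy l1 >= l2 >= l3 > 0")
        if self.label < 1:
            raise ValueError("bundle label must be a positive integer")


@dataclass
class PhantomSpec:
    """Everything needed to generate one phantom deterministically."""

    grid_shape: tuple[int, int, int] = (30, 30, 12)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 2.0)
    bundles: list[Bundle] = field(default_factory=list)
    background: float = 0.7e-3  # isotropic diffusivity, mm^2/s
    b_value: float = 1000.0  # s/mm^2
    n_directions: int = 32
    s0: float = 100.0
    noise_sigma: float = 0.0
    roi_depth: float = 3.0  # mm of each bundle end labelled as ROI
    seed: int = 0

    def __post_init__(self):
        if self.n_directions < 6:
            raise ValueError("at least 6 gradient directions required")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.background <= 0:
            raise ValueError("background diffusivity must be positive")


def gradient_scheme(n_directions: int, b_value: float) -> tuple[np.ndarray, np.ndarray]:
    """FSL-style gradient table: one leading b=0 volume + n uniform directions.

    Directions are placed by the Fibonacci spiral on the sphere, which gives a
    well-conditioned, deterministic scheme for any n >= 6.
    """
    i = np.arange(n_directions)
    golden = (1 + np.sqrt(5)) / 2
    z = 1 - (2 * i + 1) / n_directions
    theta = 2 * np.pi * i / golden
    r = np.sqrt(1 - z**2)
    dirs = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    bvecs = np.vstack([np.zeros(3), dirs])
    bvals = np.concatenate([[0.0], np.full(n_directions, b_value)])
    return bvecs, bvals


def _perp_basis(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0]) if abs(t[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(t, ref)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    return u, v


def _segment_geometry(point: np.ndarray, path: np.ndarray):
    """(distance to polyline, tangent at closest segment, arc position)."""
    best = (np.inf, None, 0.0)
    arc = 0.0
    for a, b in zip(path[:-1], path[1:]):
        seg = b - a
        seg_len = np.linalg.norm(seg)
        if seg_len == 0:
            continue
        t = seg / seg_len
        s = np.clip((point - a).dot(t), 0.0, seg_len)
        d = np.linalg.norm(point - (a + s * t))
        if d < best[0]:
            best = (d, t, arc + s)
        arc += seg_len
    return best


def make_phantom(
    spec: PhantomSpec,
) -> tuple[DiffusionVolume, TensorMaps, np.ndarray, ROIAtlas]:
    """Generate (DWI volume, ground-truth tensor maps, WM mask, ROI atlas).

    Bundle voxels carry an anisotropic tensor oriented along the local path
    tangent; everything else is isotropic background.  Each bundle with label L
    contributes two endpoint ROIs, atlas labels 2L-1 and 2L.  Rician noise of
    scale `noise_sigma` is applied per channel when nonzero.
    """
    shape = tuple(spec.grid_shape)
    vs = np.asarray(spec.voxel_size, dtype=float)
    extent = (np.array(shape) - 1) * vs
    for bundle in spec.bundles:
        if (bundle.path < -1e-9).any() or (bundle.path > extent + 1e-9).any():
            raise ValueError(
                f"bundle {bundle.label} path leaves the grid (extent {extent} mm)"
            )

    tensor = np.zeros(shape + (3, 3))
    evals = np.zeros(shape + (3,))
    evecs = np.zeros(shape + (3, 3))
    wm_mask = np.zeros(shape, dtype=bool)
    labels = np.zeros(shape, dtype=np.int16)

    iso = np.eye(3) * spec.background
    tensor[...] = iso
    evals[...] = spec.background
    evecs[...] = np.eye(3)

    idx = np.indices(shape).reshape(3, -1).T
    centers = idx * vs
    for bundle in spec.bundles:
        total_len = np.linalg.norm(np.diff(bundle.path, axis=0), axis=1).sum()
        l1, l2, l3 = bundle.eigenvalues
        for flat, center in enumerate(centers):
            i, j, k = idx[flat]
            if wm_mask[i, j, k]:
                continue  # first bundle wins on overlap
            dist, tangent, arc = _segment_geometry(center, bundle.path)
            if dist > bundle.radius or tangent is None:
                continue
            u, v = _perp_basis(tangent)
            d_vox = (
                l1 * np.outer(tangent, tangent)
                + l2 * np.outer(u, u)
                + l3 * np.outer(v, v)
            )
            tensor[i, j, k] = d_vox
            evals[i, j, k] = (l1, l2, l3)
            evecs[i, j, k] = np.column_stack([tangent, u, v])
            wm_mask[i, j, k] = True
            if arc <= spec.roi_depth:
                labels[i, j, k] = 2 * bundle.label - 1
            elif arc >= total_len - spec.roi_depth:
                labels[i, j, k] = 2 * bundle.label

    bvecs, bvals = gradient_scheme(spec.n_directions, spec.b_value)
    flat_d = tensor.reshape(-1, 3, 3)
    quad = np.einsum("gi,vij,gj->vg", bvecs, flat_d, bvecs)
    signal = spec.s0 * np.exp(-bvals[None, :] * quad)
    signal = signal.reshape(shape + (len(bvals),))
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        n1 = rng.normal(0, spec.noise_sigma, signal.shape)
        n2 = rng.normal(0, spec.noise_sigma, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)

    volume = DiffusionVolume(
        signal=signal, bvecs=bvecs, bvals=bvals, voxel_size=spec.voxel_size
    )
    fa = fa_from_eigenvalues(evals)
    truth = TensorMaps(
        eigenvalues=evals,
        eigenvectors=evecs,
        fa=fa,
        md=evals.mean(axis=-1),
        ad=evals[..., 0],
        rd=(evals[..., 1] + evals[..., 2]) / 2,
        mask=np.ones(shape, dtype=bool),
        tensor=tensor,
        voxel_size=spec.voxel_size,
    )

    present = sorted(set(np.unique(labels)) - {0})
    table = {}
    study = study_label_table()
    for lab in present:
        if lab in study:
            table[int(lab)] = study[lab]
        else:
            b = (lab + 1) // 2
            end = "a" if lab % 2 else "b"
            table[int(lab)] = (f"bundle{b}_{end}", "-", "phantom")
    atlas = ROIAtlas(labels=labels, table=table, voxel_size=spec.voxel_size)
    return volume, truth, wm_mask, atlas


def study_phantom_spec(
    noise_sigma: float = 0.0, seed: int = 0, length: float = 20.0
) -> PhantomSpec:
    """A 12-bundle phantom whose endpoint ROIs realise the 24-label study atlas.

    Twelve parallel straight bundles (one per bilateral ROI pair) run along x in
    a 4 x 3 lattice of lanes, so the expected connectome is exactly the 12
    left-right homotopic edges.
    """
    y_lanes = [4.0, 11.0, 18.0, 25.0]
    z_lanes = [2.0, 10.0, 18.0]
    bundles = []
    label = 1
    for z in z_lanes:
        for y in y_lanes:
            path = np.array([[2.0, y, z], [2.0 + length, y, z]])
            bundles.append(Bundle(path=path, radius=1.2, label=label))
            label += 1
    nx = int(np.ceil((4.0 + length) / 1.0)) + 1
    return PhantomSpec(
        grid_shape=(nx, 30, 11),
        voxel_size=(1.0, 1.0, 2.0),
        bundles=bundles,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def make_motion_trace(
    n_volumes: int, amplitude: float, seed: int = 0
) -> MotionTrace:
    """Synthetic rigid-body motion trace.

    `amplitude` is the Gaussian scale of the per-volume excursions in mm, for
    translations directly and for rotations as arc displacement at a 50 mm head
    radius (so QC behaviour is predictable from amplitude alone).  amplitude 0
    yields an all-zero trace.
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    if amplitude == 0:
        zeros = np.zeros((n_volumes, 3))
        return MotionTrace(zeros, zeros.copy())
    rng = np.random.default_rng(seed)
    translations = rng.normal(0, amplitude, (n_volumes, 3))
    rotations = rng.normal(0, amplitude / 50.0, (n_volumes, 3))
    return MotionTrace(translations, rotations)
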