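"""File formats: NIfTI volumes, FSL gradient tables, and TSV tables."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .tensor import MotionTrace
from .tracking import ConnectivityMatrix, Streamline

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_gradients",
    "load_gradients",
    "save_connectivity",
    "load_connectivity",
    "save_cohort_table",
    "load_cohort_table",
    "save_motion_trace",
    "load_motion_trace",
    "save_streamlines",
    "load_streamlines",
]

_FLOAT_FMT = "%.10g"


def save_nifti(path, array: np.ndarray, voxel_size=(1.0, 1.0, 2.0)) -> None:
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(array), affine)
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), voxel_size


def save_gradients(bval_path, bvec_path, bvals: np.ndarray, bvecs: np.ndarray) -> None:
    """FSL dialect: bvals one space-separated row; bvecs three rows x N."""
    with open(bval_path, "w") as fh:
        fh.write(" ".join(f"{b:g}" for b in bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for axis in range(3):
            fh.write(" ".join(f"{v:.10g}" for v in bvecs[:, axis]) + "\n")


def load_gradients(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    bvals = np.loadtxt(bval_path)
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] != 3:
        raise ValueError("bvecs file must have three rows (x, y, z)")
    return np.atleast_1d(bvals), bvecs.T


def save_connectivity(path_counts, path_mean_ad, matrix: ConnectivityMatrix) -> None:
    names = matrix.node_names or [f"node{i}" for i in range(matrix.n_nodes)]
    pd.DataFrame(matrix.counts, index=names, columns=names).to_csv(
        path_counts, sep="\t", float_format=_FLOAT_FMT
    )
    pd.DataFrame(matrix.mean_ad, index=names, columns=names).to_csv(
        path_mean_ad, sep="\t", float_format=_FLOAT_FMT
    )


def load_connectivity(path_counts, path_mean_ad, subject=None) -> ConnectivityMatrix:
    counts = pd.read_csv(path_counts, sep="\t", index_col=0)
    mean_ad = pd.read_csv(path_mean_ad, sep="\t", index_col=0)
    return ConnectivityMatrix(
        counts.to_numpy(dtype=int),
        mean_ad.to_numpy(dtype=float),
        node_names=list(counts.columns),
        subject=subject,
    )


def save_cohort_table(path, table: pd.DataFrame) -> None:
    cols = ["subject", "group", "age", "iq", "tiv", "ygtss", "puts"]
    table[cols].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def load_cohort_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_motion_trace(path, trace: MotionTrace) -> None:
    data = np.hstack([trace.translations, trace.rotations])
    cols = ["trans_x_mm", "trans_y_mm", "trans_z_mm", "rot_a_rad", "rot_b_rad", "rot_g_rad"]
    pd.DataFrame(data, columns=cols).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def load_motion_trace(path) -> MotionTrace:
    df = pd.read_csv(path, sep="\t")
    arr = df.to_numpy(dtype=float)
    return MotionTrace(arr[:, :3], arr[:, 3:])


def save_streamlines(path, streamlines: list[Streamline]) -> None:
    """Plain-text point lists: x y z per line, blank line between streamlines."""
    with open(path, "w") as fh:
        for sl in streamlines:
            for p in sl.points:
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
            fh.write("\n")


def load_streamlines(path) -> list[np.ndarray]:
    """Streamline point arrays from a plain-text point-list file."""
    out, cur = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            if cur:
                out.append(np.array(cur))
                cur = []
            continue
        cur.append([float(v) for v in line.split()])
    if cur:
        out.append(np.array(cur))
    return out
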