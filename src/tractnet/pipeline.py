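"""Run configuration and the end-to-end pipeline.

The default configuration reproduces the study conditions: 26 proportional
thresholds from .15 to .40 in steps of .01, 500 degree-preserving nulls per
(subject, threshold), 1000 permutations, hub criterion z >= 2, FA floor .2,
0.5 mm tracking step, 60 degree curvature stop, and the 1.5 mm / 50 mm-radius
head-motion exclusion rule.

`run_pipeline` executes: motion QC -> synthetic cohort -> graph metrics with
null normalisation -> permutation group tests with FDR -> hub detection ->
clinical association scans, writing every result table plus a manifest that
records the configuration hash and all stage seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import graphmetrics as gm
from .cohort import CohortSpec, default_cohort_spec, make_cohort
from .phantoms import make_motion_trace
from .rois import N_NODES, node_name
from .stats import (
    SCAN_METRICS,
    clinical_association_scan,
    fdr_correct,
    permutation_group_scan,
)
from .tensor import motion_qc
from .tracking import ConnectivityMatrix

__all__ = [
    "RunConfig",
    "load_config",
    "validate_inputs",
    "compute_metric_table",
    "run_pipeline",
    "stage_seed",
]

_VERSION = "0.1.0"

# fixed per-stage offsets from the master seed, so any stage can be re-run
# independently yet reproducibly
_STAGE_OFFSETS = {
    "cohort": 1,
    "motion": 2,
    "metrics": 3,
    "group": 4,
    "association_ygtss": 5,
    "association_puts": 6,
    "phantom": 7,
    "tracking": 8,
}


def stage_seed(master_seed: int, stage: str) -> int:
    return (int(master_seed) * 131 + 100003 * _STAGE_OFFSETS[stage]) % (2**31)


@dataclass
class RunConfig:
    """All tunable parameters; every default equals the study's stated value."""

    out_dir: str = "tractnet_results"
    seed: int = 0
    # cohort
    n_patients: int = 28
    n_controls: int = 30
    null_cohort: bool = False  # True drops all planted effects
    # thresholding / metrics
    threshold_min: float = 0.15
    threshold_max: float = 0.40
    threshold_step: float = 0.01
    n_null: int = 500
    hub_z: float = 2.0
    # inference
    n_perm: int = 1000
    fdr_q: float = 0.05
    uncorrected_alpha: float = 0.001
    # tractography
    fa_floor: float = 0.2
    step_mm: float = 0.5
    max_angle_deg: float = 60.0
    jitter_kappa: float = 0.0
    samples_per_seed: int = 1
    # motion QC
    motion_limit: float = 1.5
    rotation_radius_mm: float = 50.0
    motion_amplitude: float = 0.3
    motion_n_volumes: int = 33
    motion_outliers: list[str] = field(default_factory=list)
    # optional external inputs (validated when present)
    atlas_path: str | None = None
    cohort_path: str | None = None
    bval_path: str | None = None
    bvec_path: str | None = None

    def thresholds(self) -> np.ndarray:
        return gm.threshold_grid(
            self.threshold_min, self.threshold_max, self.threshold_step
        )


def load_config(path) -> RunConfig:
    """RunConfig from a YAML mapping; unknown keys rejected, missing keys
    filled with the study defaults.  An empty file yields the full default
    configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a key-value mapping")
    known = set(RunConfig.__dataclass_fields__)
    for key in raw:
        if key not in known:
            raise ValueError(f"unknown configuration key: {key!r}")
    return RunConfig(**raw)


def validate_inputs(config: RunConfig) -> dict:
    """Validation report: threshold grid, atlas label count, gradient norms,
    cohort completeness.  Returns {'ok': bool, 'problems': [...], 'n_thresholds': int}."""
    problems = []
    levels = config.thresholds()
    if not (0 < config.threshold_step and levels.size > 0):
        problems.append("threshold grid is empty or malformed")
    if not ((levels > 0) & (levels <= 1)).all():
        problems.append("threshold levels must lie in (0, 1]")
    if config.n_null < 1 or config.n_perm < 1:
        problems.append("n_null and n_perm must be positive")

    if config.atlas_path:
        from .io import load_nifti

        labels, _ = load_nifti(config.atlas_path)
        n_labels = len(set(np.unique(labels)) - {0})
        if n_labels != N_NODES:
            problems.append(
                f"atlas has {n_labels} labels; the 12-bilateral-ROI scheme "
                f"requires exactly {N_NODES}"
            )
    if config.bval_path and config.bvec_path:
        from .io import load_gradients

        bvals, bvecs = load_gradients(config.bval_path, config.bvec_path)
        norms = np.linalg.norm(bvecs[bvals > 0], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            problems.append("diffusion-weighted bvecs are not unit vectors")
        if int(np.sum(bvals == 0)) != 1:
            problems.append("gradient table must contain exactly one b=0 volume")
    if config.cohort_path:
        from .io import load_cohort_table

        table = load_cohort_table(config.cohort_path)
        for col in ("subject", "group", "age", "iq", "tiv"):
            if col not in table.columns:
                problems.append(f"cohort table lacks column {col!r}")
            elif col != "subject" and table[col].isna().any():
                problems.append(f"cohort table column {col!r} has missing values")

    return {"ok": not problems, "problems": problems, "n_thresholds": int(levels.size)}


def compute_metric_table(
    matrices: list[ConnectivityMatrix],
    thresholds: np.ndarray,
    n_null: int = 500,
    seed: int = 0,
    subjects: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nodal and global graph metrics for every (subject, threshold).

    Returns (nodal, global) long tables.  Nodal: subject, threshold, node,
    metric, value for degree, betweenness, path_length, clustering,
    local_efficiency.  Global: subject, threshold, metric, value for density,
    global_efficiency, assortativity, gamma, lambda, small_worldness.
    """
    if subjects is None:
        subjects = [
            m.subject or f"sub{i:03d}" for i, m in enumerate(matrices)
        ]
    nodal_rows, global_rows = [], []
    for s_i, (subj, mat) in enumerate(zip(subjects, matrices)):
        weights = np.asarray(mat.counts, dtype=float)
        for t_i, level in enumerate(thresholds):
            net = gm.proportional_threshold(weights, float(level))
            nodal = {
                "degree": gm.degree(net).astype(float),
                "betweenness": gm.betweenness_centrality(net),
                "path_length": gm.characteristic_path_length_nodal(net),
                "clustering": gm.clustering_coefficient(net),
                "local_efficiency": gm.local_efficiency(net),
            }
            for metric, vals in nodal.items():
                for node, val in enumerate(vals):
                    nodal_rows.append((subj, float(level), node, metric, float(val)))

            null_seed = (seed * 977 + s_i * 104729 + t_i * 7919) % (2**31)
            nulls = gm.generate_nulls(net, n_null=n_null, seed=null_seed)
            gamma, lam, sigma = gm.small_worldness(net, nulls)
            global_vals = {
                "density": gm.density(net),
                "global_efficiency": gm.global_efficiency(net),
                "assortativity": gm.assortativity(net),
                "gamma": gamma,
                "lambda": lam,
                "small_worldness": sigma,
            }
            for metric, val in global_vals.items():
                global_rows.append((subj, float(level), metric, float(val)))

    nodal_df = pd.DataFrame(
        nodal_rows, columns=["subject", "threshold", "node", "metric", "value"]
    )
    global_df = pd.DataFrame(
        global_rows, columns=["subject", "threshold", "metric", "value"]
    )
    return nodal_df, global_df


def _scan_metric_table(nodal_df: pd.DataFrame, global_df: pd.DataFrame) -> pd.DataFrame:
    """Long table over the nine scanned metrics, global metrics replicated
    across the 24 nodes so the scan family is 26 x 24 x 9 cells."""
    frames = [nodal_df[nodal_df["metric"].isin(SCAN_METRICS)]]
    glob = global_df[global_df["metric"].isin(SCAN_METRICS)]
    for node in range(N_NODES):
        g = glob.copy()
        g["node"] = node
        frames.append(g[["subject", "threshold", "node", "metric", "value"]])
    return pd.concat(frames, ignore_index=True)


def _group_tests(
    nodal_df: pd.DataFrame,
    global_df: pd.DataFrame,
    cohort: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    """Permutation GLM group tests over every metric cell, FDR per metric."""
    subjects = list(cohort["subject"])
    rows = []
    seed = stage_seed(config.seed, "group")

    cells, columns = [], []
    piv_n = nodal_df.pivot_table(
        index="subject", columns=["metric", "node", "threshold"], values="value"
    ).reindex(subjects)
    for col in piv_n.columns:
        cells.append((col[0], int(col[1]), float(col[2])))
        columns.append(piv_n[col].to_numpy(dtype=float))
    piv_g = global_df.pivot_table(
        index="subject", columns=["metric", "threshold"], values="value"
    ).reindex(subjects)
    for col in piv_g.columns:
        cells.append((col[0], -1, float(col[1])))
        columns.append(piv_g[col].to_numpy(dtype=float))

    values = np.column_stack(columns)
    finite = np.isfinite(values).all(axis=0)
    t = np.zeros(values.shape[1])
    p = np.ones(values.shape[1])
    if finite.any():
        t_f, p_f = permutation_group_scan(
            values[:, finite], cohort, n_perm=config.n_perm, seed=seed
        )
        t[finite] = t_f
        p[finite] = p_f

    out = pd.DataFrame(cells, columns=["metric", "node", "threshold"])
    out["t"] = t
    out["p"] = p
    out["p_fdr"] = np.nan
    out["significant_fdr"] = False
    for metric in out["metric"].unique():
        sel = out["metric"] == metric
        reject, p_adj = fdr_correct(out.loc[sel, "p"].to_numpy(), q=config.fdr_q)
        out.loc[sel, "p_fdr"] = p_adj
        out.loc[sel, "significant_fdr"] = reject
    out["significant_uncorrected"] = out["p"] < config.uncorrected_alpha
    out["node_name"] = [node_name(n) if n >= 0 else "-" for n in out["node"]]
    return out.sort_values(["metric", "node", "threshold"]).reset_index(drop=True)


def _hub_table(
    nodal_df: pd.DataFrame, cohort: pd.DataFrame, hub_z: float
) -> pd.DataFrame:
    """Per-group hub detection on threshold-averaged group-mean nodal metrics."""
    rows = []
    for group in ("TS", "CS"):
        members = cohort.loc[cohort["group"] == group, "subject"]
        sub = nodal_df[nodal_df["subject"].isin(members)]
        mean_deg = (
            sub[sub["metric"] == "degree"].groupby("node")["value"].mean().sort_index()
        )
        mean_bc = (
            sub[sub["metric"] == "betweenness"]
            .groupby("node")["value"]
            .mean()
            .sort_index()
        )
        hubs = gm.detect_hubs(mean_deg.to_numpy(), mean_bc.to_numpy(), z_thresh=hub_z)
        z_d = (mean_deg - mean_deg.mean()) / mean_deg.std(ddof=1)
        z_b = (mean_bc - mean_bc.mean()) / mean_bc.std(ddof=1)
        for node in hubs:
            rows.append(
                (group, int(node), node_name(int(node)), z_d[node], z_b[node])
            )
    return pd.DataFrame(
        rows, columns=["group", "node", "node_name", "z_degree", "z_betweenness"]
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write all result tables.

    Returns a summary dict with the output paths and headline numbers.  The
    same config + seed always produces byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = validate_inputs(config)
    if not report["ok"]:
        raise ValueError(f"[validate] invalid inputs: {report['problems']}")
    thresholds = config.thresholds()
    log_lines = [f"tractnet {_VERSION}"]

    # --- stage: cohort generation -----------------------------------------
    spec = (
        CohortSpec(
            n_patients=config.n_patients,
            n_controls=config.n_controls,
            seed=stage_seed(config.seed, "cohort"),
        )
        if config.null_cohort
        else default_cohort_spec(seed=stage_seed(config.seed, "cohort"))
    )
    spec.n_patients = config.n_patients
    spec.n_controls = config.n_controls
    try:
        matrices, cohort = make_cohort(spec)
    except Exception as exc:  # pragma: no cover - stage tagging only
        raise RuntimeError(f"[cohort] stage failed: {exc}") from exc
    log_lines.append(f"cohort: {config.n_patients} TS + {config.n_controls} CS")

    # --- stage: motion QC --------------------------------------------------
    motion_seed = stage_seed(config.seed, "motion")
    qc_rows, retained = [], []
    for i, subj in enumerate(cohort["subject"]):
        trace = make_motion_trace(
            config.motion_n_volumes, config.motion_amplitude, seed=motion_seed + i
        )
        if subj in config.motion_outliers:
            trace.translations[config.motion_n_volumes // 2, 0] = 2.0
        qc = motion_qc(
            trace, limit=config.motion_limit, radius=config.rotation_radius_mm
        )
        qc_rows.append(
            (subj, qc.max_translation_mm, qc.max_rotation_mm, qc.decision)
        )
        if qc.retain:
            retained.append(subj)
    qc_df = pd.DataFrame(
        qc_rows, columns=["subject", "max_trans_mm", "max_rot_mm", "decision"]
    )
    qc_df.to_csv(out / "motion_qc.tsv", sep="\t", index=False, float_format="%.10g")
    keep = cohort["subject"].isin(retained)
    cohort = cohort[keep].reset_index(drop=True)
    matrices = [m for m, k in zip(matrices, keep) if k]
    if not {"TS", "CS"} <= set(cohort["group"]):
        raise RuntimeError("[qc] stage failed: one group fully excluded by motion QC")
    log_lines.append(f"qc: retained {len(retained)} of {len(qc_rows)} subjects")

    # --- stage: connectivity matrices --------------------------------------
    from .io import save_cohort_table, save_connectivity

    conn_dir = out / "connectomes"
    conn_dir.mkdir(exist_ok=True)
    for mat in matrices:
        save_connectivity(
            conn_dir / f"{mat.subject}_counts.tsv",
            conn_dir / f"{mat.subject}_mean_ad.tsv",
            mat,
        )
    save_cohort_table(out / "cohort.tsv", cohort)

    # --- stage: graph metrics ----------------------------------------------
    try:
        nodal_df, global_df = compute_metric_table(
            matrices,
            thresholds,
            n_null=config.n_null,
            seed=stage_seed(config.seed, "metrics"),
            subjects=list(cohort["subject"]),
        )
    except Exception as exc:
        raise RuntimeError(f"[metrics] stage failed: {exc}") from exc
    nodal_df.to_csv(out / "nodal_metrics.tsv", sep="\t", index=False, float_format="%.10g")
    global_df.to_csv(
        out / "global_metrics.tsv", sep="\t", index=False, float_format="%.10g"
    )
    log_lines.append(
        f"metrics: {len(thresholds)} thresholds x {len(matrices)} subjects, "
        f"{config.n_null} nulls per cell"
    )

    # --- stage: group inference --------------------------------------------
    try:
        group_df = _group_tests(nodal_df, global_df, cohort, config)
    except Exception as exc:
        raise RuntimeError(f"[group] stage failed: {exc}") from exc
    group_df.to_csv(out / "group_results.tsv", sep="\t", index=False, float_format="%.10g")

    hubs_df = _hub_table(nodal_df, cohort, config.hub_z)
    hubs_df.to_csv(out / "hubs.tsv", sep="\t", index=False, float_format="%.10g")

    # --- stage: clinical association scans ---------------------------------
    scan_df = _scan_metric_table(nodal_df, global_df)
    assoc_frames = []
    for score in ("ygtss", "puts"):
        try:
            assoc = clinical_association_scan(
                scan_df,
                cohort,
                score,
                thresholds=thresholds,
                n_perm=config.n_perm,
                seed=stage_seed(config.seed, f"association_{score}"),
                fdr_q=config.fdr_q,
            )
        except Exception as exc:
            raise RuntimeError(f"[association:{score}] stage failed: {exc}") from exc
        assoc_frames.append(assoc)
    assoc_df = pd.concat(assoc_frames, ignore_index=True)
    assoc_df["significant_uncorrected"] = assoc_df["p"] < config.uncorrected_alpha
    assoc_df.to_csv(
        out / "association_results.tsv", sep="\t", index=False, float_format="%.10g"
    )
    log_lines.append(
        f"association: {len(assoc_frames[0])} cells per clinical score"
    )

    # --- manifest -----------------------------------------------------------
    cfg_dict = asdict(config)
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    manifest = {
        "version": _VERSION,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE_OFFSETS},
        "n_thresholds": int(len(thresholds)),
        "n_subjects_retained": int(len(cohort)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")

    return {
        "out_dir": str(out),
        "n_retained": len(cohort),
        "n_group_cells": len(group_df),
        "n_association_cells": len(assoc_frames[0]),
        "hubs": {
            g: sorted(hubs_df.loc[hubs_df["group"] == g, "node_name"])
            for g in ("TS", "CS")
        },
        "manifest": manifest,
    }
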