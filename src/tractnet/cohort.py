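"""Synthetic two-group connectome cohorts with planted effects.

Generates per-subject 24x24 streamline-count matrices (with parallel mean-AD
edge weights) plus a cohort covariate table, emulating a patient/control study
of n = 28 vs 30 matched adolescents:

* a fixed group-level "anatomical backbone" of edge weights shared by all
  subjects (real cohorts share one anatomy), with lognormal subject-level
  variation on every edge;
* two hub nodes (right putamen, left SMA) with inflated connection strength in
  BOTH groups;
* an optional group difference in one nodal graph metric, planted by scaling
  the target node's incident edge weights in patients, with the scale factor
  calibrated by Monte-Carlo simulation to a requested standardized effect size;
* optional linear associations between clinical scores and nodal graph metrics
  after age/IQ/TIV adjustment, planted by drawing each patient's score as a
  linear function of their realized z-scored metric plus noise.

Clinical scores (YGTSS tic severity, PUTS premonitory-urge score) are emitted
for patients only; controls carry missing values, matching the study design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from . import graphmetrics as gm
from .rois import N_NODES, node_index, node_name
from .tracking import ConnectivityMatrix

__all__ = [
    "GroupEffect",
    "ClinicalEffect",
    "CohortSpec",
    "make_cohort",
    "calibrate_group_effect",
    "nodal_metric_values",
    "default_cohort_spec",
]

# threshold at which planted effect sizes are defined and measured
REFERENCE_LEVEL = 0.25

# fixed RNG roots: the anatomical backbone and the calibration simulation are
# deliberately seed-independent so the same study conditions underlie every
# seeded cohort realisation
_TEMPLATE_ROOT = 913370
_CALIBRATION_ROOT = 913371

_METRIC_FUNCS = {
    "degree": lambda net: gm.degree(net).astype(float),
    "betweenness": gm.betweenness_centrality,
    "path_length": gm.characteristic_path_length_nodal,
    "clustering": gm.clustering_coefficient,
    "local_efficiency": gm.local_efficiency,
}


@dataclass(frozen=True)
class GroupEffect:
    """Planted patient-vs-control difference in one nodal metric.

    effect_size is Cohen's d of the patient-minus-control difference at the
    reference threshold; its sign sets the direction.
    """

    node: int
    metric: str
    effect_size: float

    def __post_init__(self):
        if self.metric not in _METRIC_FUNCS:
            raise ValueError(f"unknown nodal metric {self.metric!r}")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")


@dataclass(frozen=True)
class ClinicalEffect:
    """Planted covariate-adjusted association between a clinical score and a metric.

    effect_size is on the correlation scale (standardized slope of the score on
    the z-scored metric); its sign sets the slope sign.
    """

    node: int
    metric: str
    score: str  # 'ygtss' or 'puts'
    effect_size: float

    def __post_init__(self):
        if self.metric not in _METRIC_FUNCS:
            raise ValueError(f"unknown nodal metric {self.metric!r}")
        if self.score not in ("ygtss", "puts"):
            raise ValueError("clinical score must be 'ygtss' or 'puts'")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")


@dataclass
class CohortSpec:
    """Conditions of one synthetic cohort realisation."""

    n_patients: int = 28
    n_controls: int = 30
    n_nodes: int = N_NODES
    weight_mu: float = 3.2  # lognormal log-mean of backbone streamline counts
    weight_sigma: float = 0.6  # lognormal log-sd of the backbone
    subject_sigma: float = 0.3  # lognormal log-sd of per-subject edge variation
    hub_nodes: tuple[int, ...] = ()
    hub_strength: float = 2.0  # multiplier on hub-incident backbone weights
    group_effect: GroupEffect | None = None
    clinical_effects: tuple[ClinicalEffect, ...] = ()
    age_range: tuple[float, float] = (8.6, 21.8)  # years
    iq_mean: float = 115.0
    iq_sd: float = 13.0
    tiv_mean: float = 1.45e6  # mm^3
    tiv_sd: float = 1.3e5
    ad_mean: float = 1.1e-3  # mm^2/s, edge mean-AD weights
    ad_sd: float = 5e-5
    age_coupling: float = 0.3  # standardized age term inside clinical scores
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes != N_NODES:
            raise ValueError(f"cohort networks have {N_NODES} nodes")
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("both groups need at least 2 subjects")
        for h in self.hub_nodes:
            if not 0 <= h < self.n_nodes:
                raise ValueError(f"hub node {h} outside [0, {self.n_nodes - 1}]")
        planted = []
        if self.group_effect is not None:
            if not 0 <= self.group_effect.node < self.n_nodes:
                raise ValueError("group effect node outside the network")
        for eff in self.clinical_effects:
            if not 0 <= eff.node < self.n_nodes:
                raise ValueError("clinical effect node outside the network")
            key = (eff.node, eff.metric, eff.score)
            if key in planted:
                raise ValueError(
                    f"effect planted twice for node {eff.node}, metric "
                    f"{eff.metric!r}, score {eff.score!r}"
                )
            planted.append(key)


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The default study conditions: hubs at right putamen and left SMA, an
    elevated left-putamen betweenness in patients, and local-efficiency /
    betweenness associations with PUTS / YGTSS at insular, caudate, thalamic
    and motor nodes."""
    return CohortSpec(
        hub_nodes=(node_index("R_putamen"), node_index("L_SMA")),
        group_effect=GroupEffect(node_index("L_putamen"), "betweenness", 1.2),
        clinical_effects=(
            ClinicalEffect(node_index("L_caudate"), "local_efficiency", "puts", -0.55),
            ClinicalEffect(
                node_index("R_posterior_insula"), "local_efficiency", "puts", 0.55
            ),
            ClinicalEffect(
                node_index("L_anterior_insula"), "local_efficiency", "puts", 0.60
            ),
            ClinicalEffect(node_index("L_thalamus"), "betweenness", "ygtss", 0.60),
            ClinicalEffect(node_index("R_M1"), "betweenness", "ygtss", 0.60),
        ),
        seed=seed,
    )


def _backbone(spec: CohortSpec) -> np.ndarray:
    """Seed-independent group-level edge-weight template (shared anatomy)."""
    rng = np.random.default_rng([_TEMPLATE_ROOT, spec.n_nodes])
    n = spec.n_nodes
    iu, ju = np.triu_indices(n, 1)
    base = np.zeros((n, n))
    base[iu, ju] = rng.lognormal(spec.weight_mu, spec.weight_sigma, iu.size)
    base += base.T
    for h in spec.hub_nodes:
        base[h, :] *= spec.hub_strength
        base[:, h] *= spec.hub_strength
        base[h, h] = 0.0
    return base


def _subject_weights(
    base: np.ndarray, spec: CohortSpec, rng: np.random.Generator
) -> np.ndarray:
    n = base.shape[0]
    iu, ju = np.triu_indices(n, 1)
    noise = np.zeros((n, n))
    noise[iu, ju] = rng.lognormal(0.0, spec.subject_sigma, iu.size)
    noise += noise.T
    return base * noise


def _apply_surgery(weights: np.ndarray, node: int, scale: float) -> np.ndarray:
    out = weights.copy()
    out[node, :] *= scale
    out[:, node] *= scale
    out[node, node] = 0.0
    return out


def nodal_metric_values(
    matrices: list[ConnectivityMatrix] | list[np.ndarray],
    node: int,
    metric: str,
    level: float = REFERENCE_LEVEL,
) -> np.ndarray:
    """Per-subject value of one nodal metric at one proportional threshold."""
    func = _METRIC_FUNCS[metric]
    out = np.empty(len(matrices))
    for i, mat in enumerate(matrices):
        counts = mat.counts if isinstance(mat, ConnectivityMatrix) else mat
        net = gm.proportional_threshold(np.asarray(counts, dtype=float), level)
        out[i] = func(net)[node]
    return out


def _cohens_d(patients: np.ndarray, controls: np.ndarray) -> float:
    n1, n2 = len(patients), len(controls)
    pooled = np.sqrt(
        ((n1 - 1) * patients.var(ddof=1) + (n2 - 1) * controls.var(ddof=1))
        / (n1 + n2 - 2)
    )
    if pooled == 0:
        return 0.0
    return float((patients.mean() - controls.mean()) / pooled)


def _simulated_d(spec: CohortSpec, scale: float, n_per_group: int) -> float:
    """Effect size produced by surgery `scale` under the cohort's generative law.

    Uses a fixed calibration RNG (common random numbers across candidate
    scales, so d(scale) is a smooth, nearly monotone function).
    """
    eff = spec.group_effect
    base = _backbone(spec)
    rng = np.random.default_rng([_CALIBRATION_ROOT, spec.n_nodes, n_per_group])

    def _as_counts(w: np.ndarray) -> np.ndarray:
        c = np.floor(w + 0.5)  # same integer rounding as make_cohort
        np.fill_diagonal(c, 0)
        return c

    pat, con = [], []
    for _ in range(n_per_group):
        con.append(_as_counts(_subject_weights(base, spec, rng)))
    for _ in range(n_per_group):
        pat.append(
            _as_counts(_apply_surgery(_subject_weights(base, spec, rng), eff.node, scale))
        )
    vals_p = nodal_metric_values(pat, eff.node, eff.metric)
    vals_c = nodal_metric_values(con, eff.node, eff.metric)
    return _cohens_d(vals_p, vals_c)


@lru_cache(maxsize=32)
def _calibrate_cached(spec_key: tuple, n_per_group: int) -> float:
    spec = CohortSpec(**dict(spec_key))
    eff = spec.group_effect
    target = eff.effect_size
    if target == 0:
        return 1.0

    # orientation probe: does scaling incident edges up push the metric the
    # right way, or must we scale down?
    probe = _simulated_d(spec, 1.8, n_per_group)
    upward = (probe >= 0) == (target >= 0)

    def scale_of(alpha: float) -> float:
        return 1.0 + alpha if upward else 1.0 / (1.0 + alpha)

    goal = abs(target)
    sign = 1.0 if target >= 0 else -1.0
    # common-random-numbers baseline at no perturbation; subtracting it
    # removes the shared Monte-Carlo offset from every d estimate
    d_base = sign * _simulated_d(spec, 1.0, n_per_group)
    lo, d_lo = 0.0, 0.0
    hi = None
    for alpha in (0.1, 0.2, 0.4, 0.8, 1.6, 3.2, 6.4):
        d = sign * _simulated_d(spec, scale_of(alpha), n_per_group) - d_base
        if d >= goal:
            hi = alpha
            break
        lo, d_lo = alpha, d
    if hi is None:
        warnings.warn(
            f"calibration could not reach |d| = {goal:.2f} (got {d_lo:.2f}); "
            "using the largest probed perturbation",
            stacklevel=2,
        )
        return scale_of(6.4)
    for _ in range(6):
        mid = 0.5 * (lo + hi)
        d = sign * _simulated_d(spec, scale_of(mid), n_per_group) - d_base
        if d >= goal:
            hi = mid
        else:
            lo = mid
    return scale_of(0.5 * (lo + hi))


def _spec_key(spec: CohortSpec) -> tuple:
    """Hashable spec identity for calibration caching; the cohort seed is
    excluded because calibration is seed-independent by design."""
    d = {
        "n_nodes": spec.n_nodes,
        "weight_mu": spec.weight_mu,
        "weight_sigma": spec.weight_sigma,
        "subject_sigma": spec.subject_sigma,
        "hub_nodes": tuple(spec.hub_nodes),
        "hub_strength": spec.hub_strength,
        "group_effect": spec.group_effect,
    }
    return tuple(sorted(d.items(), key=lambda kv: kv[0]))


def calibrate_group_effect(spec: CohortSpec, n_per_group: int = 150) -> float:
    """Edge-weight scale factor realising the spec's planted group effect size.

    Found by bisection on Monte-Carlo estimates of Cohen's d under the cohort's
    generative law; deterministic for given spec parameters and cached, so
    repeated cohorts under the same conditions share one calibration.
    """
    if spec.group_effect is None or spec.group_effect.effect_size == 0:
        return 1.0
    return _calibrate_cached(_spec_key(spec), n_per_group)


def make_cohort(
    spec: CohortSpec, edge_scale: float | None = None
) -> tuple[list[ConnectivityMatrix], pd.DataFrame]:
    """Generate the cohort: connectivity matrices and the covariate table.

    `edge_scale` overrides the calibrated surgery scale (pass the value from
    :func:`calibrate_group_effect` to skip recalibration in replicate loops).
    Returns (matrices, table); the table has columns
    subject, group, age, iq, tiv, ygtss, puts with clinical scores for
    patients only.
    """
    base = _backbone(spec)
    if edge_scale is None:
        edge_scale = calibrate_group_effect(spec)

    n_p, n_c = spec.n_patients, spec.n_controls
    n = spec.n_nodes
    rng_edges = np.random.default_rng([spec.seed, 2])
    rng_cov = np.random.default_rng([spec.seed, 3])
    rng_clin = np.random.default_rng([spec.seed, 4])
    rng_ad = np.random.default_rng([spec.seed, 5])

    subjects, groups, weights = [], [], []
    for i in range(n_p):
        w = _subject_weights(base, spec, rng_edges)
        if spec.group_effect is not None and edge_scale != 1.0:
            w = _apply_surgery(w, spec.group_effect.node, edge_scale)
        weights.append(w)
        subjects.append(f"TS{i + 1:02d}")
        groups.append("TS")
    for i in range(n_c):
        weights.append(_subject_weights(base, spec, rng_edges))
        subjects.append(f"CS{i + 1:02d}")
        groups.append("CS")

    names = [node_name(v) for v in range(n)]
    matrices = []
    for subj, w in zip(subjects, weights):
        counts = np.floor(w + 0.5).astype(int)
        counts = np.maximum(counts, 0)
        np.fill_diagonal(counts, 0)
        counts = np.triu(counts, 1)
        counts = counts + counts.T
        ad = np.zeros((n, n))
        iu, ju = np.triu_indices(n, 1)
        vals = np.abs(rng_ad.normal(spec.ad_mean, spec.ad_sd, iu.size))
        ad[iu, ju] = vals
        ad += ad.T
        ad[counts == 0] = 0.0
        matrices.append(
            ConnectivityMatrix(counts, ad, node_names=names, subject=subj)
        )

    n_tot = n_p + n_c
    age = rng_cov.uniform(*spec.age_range, n_tot)
    iq = rng_cov.normal(spec.iq_mean, spec.iq_sd, n_tot)
    tiv = np.abs(rng_cov.normal(spec.tiv_mean, spec.tiv_sd, n_tot))

    table = pd.DataFrame(
        {
            "subject": subjects,
            "group": groups,
            "age": age,
            "iq": iq,
            "tiv": tiv,
            "ygtss": np.nan,
            "puts": np.nan,
        }
    )

    # clinical scores for patients only, built from realized metrics so the
    # requested adjusted associations hold
    pat_mats = matrices[:n_p]
    z_age = (age[:n_p] - age[:n_p].mean()) / max(age[:n_p].std(ddof=1), 1e-12)
    score_scale = {"ygtss": (33.0, 15.3, 0.0, 100.0), "puts": (20.4, 5.8, 9.0, 36.0)}
    for score in ("ygtss", "puts"):
        effects = [e for e in spec.clinical_effects if e.score == score]
        z_total = spec.age_coupling * z_age
        var_used = spec.age_coupling**2
        for eff in effects:
            vals = nodal_metric_values(pat_mats, eff.node, eff.metric)
            sd = vals.std(ddof=1)
            if sd == 0:
                warnings.warn(
                    f"metric {eff.metric!r} at node {eff.node} is constant; "
                    f"cannot plant association with {score}",
                    stacklevel=2,
                )
                continue
            z_total = z_total + eff.effect_size * (vals - vals.mean()) / sd
            var_used += eff.effect_size**2
        resid = np.sqrt(max(0.1, 1.0 - var_used))
        z_total = z_total + resid * rng_clin.standard_normal(n_p)
        mean, sd, lo, hi = score_scale[score]
        raw = np.clip(np.floor(mean + sd * z_total + 0.5), lo, hi)
        table.loc[: n_p - 1, score] = raw

    return matrices, table
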