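"""Permutation group comparison, clinical-association scan, and FDR correction.

Group differences in graph metrics are tested with a general linear model
(group + age + IQ + TIV) whose group-term t statistic is referred to a
Freedman–Lane permutation null: the metric is residualized against the
covariate-only reduced model, the residuals are permuted, refitted under the
full model, and p = (1 + #{|t*| >= |t|}) / (1 + n_perm).

Clinical associations are scanned in patients only: at every (threshold, node,
metric) cell the clinical score is regressed on the metric with age, IQ and
TIV as covariates; one scan covers 26 x 24 x 9 = 5,616 cells, corrected as a
single family by the Benjamini–Hochberg false discovery rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .graphmetrics import GLOBAL_METRICS, NODAL_METRICS

__all__ = [
    "GroupTestResult",
    "permutation_group_test",
    "permutation_group_scan",
    "clinical_association_scan",
    "fdr_correct",
]

COVARIATES = ("age", "iq", "tiv")
SCAN_METRICS = NODAL_METRICS + GLOBAL_METRICS  # the nine scanned metrics


@dataclass
class GroupTestResult:
    t: float
    p: float
    beta: float
    df: int
    n_perm: int


def _check_cohort(cohort: pd.DataFrame) -> None:
    for col in ("group",) + COVARIATES:
        if col not in cohort.columns:
            raise ValueError(f"cohort table lacks required column {col!r}")
    if cohort[list(COVARIATES)].isna().any().any():
        raise ValueError("covariates must be complete for all included subjects")
    groups = set(cohort["group"])
    if not groups == {"TS", "CS"}:
        if not ({"TS", "CS"} & groups) or len(groups) < 2:
            raise ValueError("both groups (TS and CS) must be nonempty")


def _design_matrices(cohort: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(full design with group in column 1, reduced covariate-only design)."""
    g = (cohort["group"].to_numpy() == "TS").astype(float)
    covs = cohort[list(COVARIATES)].to_numpy(dtype=float)
    ones = np.ones(len(cohort))
    full = np.column_stack([ones, g, covs])
    reduced = np.column_stack([ones, covs])
    return full, reduced


def _t_for_column(x: np.ndarray, y: np.ndarray, col: int) -> tuple[float, float, int]:
    """(beta, t, df) of design column `col` under OLS; y may be 2D (n, k)."""
    n, p = x.shape
    pinv = np.linalg.pinv(x)
    beta = pinv @ y
    resid = y - x @ beta
    df = n - p
    sse = (resid**2).sum(axis=0)
    xtx_inv = np.linalg.pinv(x.T @ x)
    var = sse / df * xtx_inv[col, col]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[col] / np.sqrt(var)
    return beta[col], t, df


def _freedman_lane(
    y: np.ndarray,
    full: np.ndarray,
    reduced: np.ndarray,
    col: int,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, int, np.ndarray]:
    """Observed (beta, t) plus the permutation t distribution for one design.

    y: (n,) or (n, k) — the permutation schedule is shared across columns of y.
    Returns (beta_obs, t_obs, df, t_null of shape (n_perm, k)).
    """
    y = np.atleast_2d(y.T).T  # (n, k)
    n = y.shape[0]
    beta_obs, t_obs, df = _t_for_column(full, y, col)

    pinv_r = np.linalg.pinv(reduced)
    fitted = reduced @ (pinv_r @ y)
    resid = y - fitted

    pinv_f = np.linalg.pinv(full)
    xtx_gg = np.linalg.pinv(full.T @ full)[col, col]
    p_full = full.shape[1]

    t_null = np.empty((n_perm, y.shape[1]))
    for b in range(n_perm):
        perm = rng.permutation(n)
        y_star = fitted + resid[perm]
        beta_star = pinv_f @ y_star
        r_star = y_star - full @ beta_star
        sse = (r_star**2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_null[b] = beta_star[col] / np.sqrt(sse / (n - p_full) * xtx_gg)
    return beta_obs, t_obs, df, t_null


def permutation_group_test(
    values: np.ndarray,
    cohort: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> GroupTestResult:
    """Permutation GLM test of a group difference with nuisance covariates.

    `values` holds one metric value per cohort row.  A constant metric yields
    p = 1 with a warning; a singular full design raises.
    """
    _check_cohort(cohort)
    y = np.asarray(values, dtype=float)
    if y.shape != (len(cohort),):
        raise ValueError("values must align with the cohort rows")
    if np.ptp(y) == 0:
        warnings.warn("metric constant across subjects; p = 1", stacklevel=2)
        return GroupTestResult(t=0.0, p=1.0, beta=0.0, df=len(y) - 5, n_perm=n_perm)

    full, reduced = _design_matrices(cohort)
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError("singular design matrix (collinear covariates?)")

    rng = np.random.default_rng(seed)
    beta, t, df, t_null = _freedman_lane(y, full, reduced, 1, n_perm, rng)
    p = (1.0 + np.sum(np.abs(t_null[:, 0]) >= np.abs(t[0]))) / (1.0 + n_perm)
    return GroupTestResult(
        t=float(t[0]), p=float(p), beta=float(beta[0]), df=df, n_perm=n_perm
    )


def permutation_group_scan(
    values: np.ndarray,
    cohort: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized group test over many metrics at once.

    values: (n_subjects, n_tests).  One permutation schedule is shared across
    tests (as in standard neuroimaging permutation tools).  Returns (t, p)
    arrays of length n_tests; constant columns get t = 0, p = 1.
    """
    _check_cohort(cohort)
    y = np.asarray(values, dtype=float)
    if y.ndim != 2 or y.shape[0] != len(cohort):
        raise ValueError("values must be (n_subjects, n_tests)")
    full, reduced = _design_matrices(cohort)
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError("singular design matrix (collinear covariates?)")

    constant = np.ptp(y, axis=0) == 0
    rng = np.random.default_rng(seed)
    beta, t, df, t_null = _freedman_lane(y, full, reduced, 1, n_perm, rng)
    t = np.where(constant, 0.0, t)
    exceed = (np.abs(t_null) >= np.abs(t)[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)
    p = np.where(constant, 1.0, p)
    return t, p


def clinical_association_scan(
    metrics: pd.DataFrame,
    cohort: pd.DataFrame,
    score: str,
    thresholds: np.ndarray | None = None,
    n_perm: int = 0,
    seed: int = 0,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Regression of one clinical score on every (threshold, node, metric) cell.

    `metrics` is a long table (subject, threshold, node, metric, value) with
    global metrics replicated across nodes; patients are selected from the
    cohort (group TS with a recorded score).  Each cell fits
    score ~ metric + age + IQ + TIV and records the metric-term beta, t and
    parametric p; with n_perm > 0 a Freedman–Lane permutation p is added.
    The returned table carries BH-FDR-adjusted p over the whole scan family.
    """
    if score not in cohort.columns:
        raise ValueError(f"cohort table lacks clinical score {score!r}")
    patients = cohort[(cohort["group"] == "TS") & cohort[score].notna()]
    if patients.empty:
        raise ValueError("no patients with a recorded clinical score")
    for col in COVARIATES:
        if patients[col].isna().any():
            raise ValueError("covariates must be complete for all patients")

    subj = list(patients["subject"])
    y = patients[score].to_numpy(dtype=float)
    covs = patients[list(COVARIATES)].to_numpy(dtype=float)
    n = len(subj)
    if n < 6:
        raise ValueError("fewer patients than regression parameters + 1")

    cube = metrics[metrics["subject"].isin(subj)].pivot_table(
        index="subject", columns=["threshold", "node", "metric"], values="value"
    )
    cube = cube.reindex(subj)
    if thresholds is None:
        thresholds = np.array(sorted(metrics["threshold"].unique()))
    nodes = np.array(sorted(metrics["node"].unique()))

    ones = np.ones(n)
    reduced = np.column_stack([ones, covs])
    rng = np.random.default_rng(seed)
    if n_perm > 0:
        pinv_r = np.linalg.pinv(reduced)
        fitted = reduced @ (pinv_r @ y)
        resid = y - fitted
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        y_star = fitted[None, :] + resid[perms]  # (n_perm, n)

    rows = []
    for thr in thresholds:
        for node in nodes:
            for metric in SCAN_METRICS:
                key = (thr, node, metric)
                if key not in cube.columns:
                    raise ValueError(f"metric table lacks cell {key}")
                m = cube[key].to_numpy(dtype=float)
                if not np.isfinite(m).all() or np.ptp(m) == 0:
                    rows.append((thr, node, metric, np.nan, np.nan, 1.0, np.nan))
                    continue
                x = np.column_stack([ones, m, covs])
                beta, t, df = _t_for_column(x, y[:, None], 1)
                p_param = 2 * sps.t.sf(abs(float(t[0])), df)
                p_perm = np.nan
                if n_perm > 0:
                    pinv_f = np.linalg.pinv(x)
                    xtx_gg = np.linalg.pinv(x.T @ x)[1, 1]
                    b_star = pinv_f @ y_star.T  # (5, n_perm)
                    r_star = y_star.T - x @ b_star
                    sse = (r_star**2).sum(axis=0)
                    with np.errstate(divide="ignore", invalid="ignore"):
                        t_star = b_star[1] / np.sqrt(sse / df * xtx_gg)
                    p_perm = (1.0 + np.sum(np.abs(t_star) >= abs(float(t[0])))) / (
                        1.0 + n_perm
                    )
                rows.append(
                    (thr, node, metric, float(beta[0]), float(t[0]), p_param, p_perm)
                )

    out = pd.DataFrame(
        rows, columns=["threshold", "node", "metric", "beta", "t", "p", "p_perm"]
    )
    reject, p_adj = fdr_correct(out["p"].to_numpy(), q=fdr_q)
    out["p_fdr"] = p_adj
    out["significant_fdr"] = reject
    out["score"] = score
    return out


def fdr_correct(
    p_values: np.ndarray, q: float = 0.05, method: str = "bh"
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg (or Benjamini–Yekutieli) step-up FDR correction.

    Returns (rejection mask, adjusted p-values).  Empty input -> empty output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}[method]
    reject, p_adj, _, _ = multipletests(p, alpha=q, method=sm_method)
    return reject, p_adj
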