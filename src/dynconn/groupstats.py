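"""Case-control statistics on connectivity edges and state temporal metrics.

Edge-wise comparisons regress age and sex from each edge (a single pooled
regression per edge, intercept included), then apply a two-tailed two-sample
t-test to the residuals, with Benjamini-Hochberg FDR correction across the
edge family. Dwell time and fractional occupancy are compared with ANCOVA
(metric ~ group + age + sex); the group coefficient's t and two-tailed p are
reported.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

__all__ = ["residual_ttest", "ancova_group_effect", "bh_fdr"]

logger = logging.getLogger(__name__)


def _validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    required = {"subject_id", "group", "age", "sex"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if cohort[["age", "sex"]].isna().any().any():
        raise ValueError("missing covariates in cohort table")
    groups = set(cohort["group"])
    if groups != {"case", "control"}:
        raise ValueError(f"expected groups case/control, got {sorted(groups)}")
    return cohort


def residual_ttest(
    edges: pd.DataFrame,
    cohort: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Edge-wise case-control t-tests on age/sex-regressed residuals, with FDR.

    ``edges`` is subjects x edges (index = subject_id). Per edge the value is
    regressed on [1, age, sex] with both groups pooled; the residuals enter a
    two-tailed two-sample t-test (equal variances, df = n1 + n2 − 2). q values
    are Benjamini-Hochberg across all edges; significance is judged on q only.
    """
    cohort = _validate_cohort(cohort).set_index("subject_id").loc[edges.index]
    for g in ("case", "control"):
        if (cohort["group"] == g).sum() < 3:
            raise ValueError(f"need at least 3 subjects in group {g!r}")
    z = np.column_stack([
        np.ones(len(cohort)), cohort["age"].to_numpy(float), cohort["sex"].to_numpy(float),
    ])
    if np.linalg.matrix_rank(z) < z.shape[1]:
        raise ValueError("rank-deficient covariate matrix (age/sex collinear)")
    y = edges.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(z, y, rcond=None)
    resid = y - z @ beta
    is_case = (cohort["group"] == "case").to_numpy()
    t, p = stats.ttest_ind(resid[is_case], resid[~is_case], axis=0)
    q = bh_fdr(p)
    return pd.DataFrame(
        {
            "edge": edges.columns,
            "t_statistic": t,
            "p_uncorrected": p,
            "q_fdr": q,
            "significant_fdr": q < alpha,
        }
    )


def ancova_group_effect(metric: pd.Series, cohort: pd.DataFrame) -> tuple[float, float]:
    """ANCOVA group effect on one temporal metric: metric ~ group + age + sex.

    Subjects with an undefined metric (e.g. dwell time of a state they never
    visited) are dropped with a log entry, not imputed. Returns the group
    coefficient's (t, two-tailed p); group is coded case = 1.
    """
    cohort = _validate_cohort(cohort).set_index("subject_id")
    metric = metric.dropna()
    dropped = set(cohort.index) - set(metric.index)
    if dropped:
        logger.info("ANCOVA: dropping %d subjects with undefined metric: %s",
                    len(dropped), sorted(dropped))
    sub = cohort.loc[metric.index]
    for g in ("case", "control"):
        if (sub["group"] == g).sum() < 3:
            raise ValueError(f"fewer than 3 subjects with defined metric in group {g!r}")
    x = pd.DataFrame(
        {
            "group": (sub["group"] == "case").astype(float),
            "age": sub["age"].astype(float),
            "sex": sub["sex"].astype(float),
        }
    )
    model = sm.OLS(metric.to_numpy(float), sm.add_constant(x)).fit()
    return float(model.tvalues["group"]), float(model.pvalues["group"])


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q values (monotone, q >= p)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
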