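"""The statistical battery applied to pattern counts, graph metrics and
clinical covariates.

Fisher's exact test compares pattern-label counts between periods; paired
Student's t-tests compare each graph metric between periods per band; partial
correlation (residualization against age, sex and disease duration) relates
metrics to clinical features; Bonferroni and Benjamini-Hochberg FDR control
the 7-band x 4-metric family, and significance is flagged by the stricter of
the two corrections by default.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import CollinearityError, DegenerateTestError


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 contingency table (fixed margins,
    summing hypergeometric probabilities <= that of the observed table)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if not np.all(t == np.floor(t)):
            raise ValueError("table entries must be nonnegative integers")
        t = t.astype(int)
        if np.any(t < 0):
            raise ValueError("table entries must be nonnegative integers")
    if t.sum() == 0:
        raise ValueError("table total must be positive")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def metric_t_test(
    values_a, values_b, paired: bool = True
) -> tuple[float, float]:
    """Student's t-test between two samples of a network parameter.

    Paired by default (ictal and termination segments come from the same
    seizure).  Identical paired samples report (0, 1); constant nonzero
    paired differences (or two zero-variance groups) are degenerate and raise
    rather than return 0/0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired:
        if a.shape != b.shape or a.size < 2:
            raise ValueError("paired test needs equal-length samples of size >= 2")
        d = a - b
        if np.ptp(d) == 0:
            if d[0] == 0:  # identical samples: no difference at all
                return 0.0, 1.0
            raise DegenerateTestError("paired differences have zero variance")
        res = sps.ttest_rel(a, b)
    else:
        if a.size < 2 or b.size < 2:
            raise ValueError("each group needs >= 2 values")
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            raise DegenerateTestError("both groups have zero variance")
        res = sps.ttest_ind(a, b)
    return float(res.statistic), float(res.pvalue)


def partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized by least squares against [1, covariates];
    the correlation of the residuals is returned with a two-sided p from
    t = r*sqrt(df)/sqrt(1-r^2), df = n - 2 - n_covariates.  With no covariates
    this reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        Z = np.empty((n, 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if Z.shape[0] != n:
            raise ValueError("covariates must have one row per observation")
    k = Z.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > n_covariates + 2 (n={n}, covariates={k})")
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("covariate matrix is rank deficient")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    sx = np.sqrt(rx @ rx)
    sy = np.sqrt(ry @ ry)
    # residuals that vanish to rounding noise mean the variable is fully
    # explained by the covariates: the partial correlation is 0 by convention
    tol_x = 1e-10 * max(1.0, float(np.linalg.norm(x)))
    tol_y = 1e-10 * max(1.0, float(np.linalg.norm(y)))
    if sx <= tol_x or sy <= tol_y:
        return 0.0, 1.0
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), df=df))
    return r, p


def _check_pvalues(p_list) -> np.ndarray:
    p = np.asarray(p_list, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be a 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bonferroni(p_list) -> np.ndarray:
    """Bonferroni adjustment: min(1, m*p), order preserving."""
    p = _check_pvalues(p_list)
    if p.size == 0:
        return p
    return np.minimum(1.0, p * p.size)


def bh_fdr(p_list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = _check_pvalues(p_list)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def encode_sex(sex) -> np.ndarray:
    """Numeric sex coding for covariate adjustment: M=1, F=0 (any consistent
    coding gives the same |r|)."""
    return np.asarray([1.0 if s == "M" else 0.0 for s in sex])


def summarize_clinical(clinical) -> dict:
    """Cohort summary: n, male count, mean and sample SD (n-1 denominator) of
    age, disease duration and seizure frequency.  SD is NaN for n = 1."""
    n = len(clinical)
    if n == 0:
        raise ValueError("clinical table is empty")
    out = {"n": int(n), "n_male": int((clinical["sex"] == "M").sum())}
    for col, key in (
        ("age_years", "age"),
        ("duration_months", "duration"),
        ("seizure_freq_per_day", "seizure_freq"),
    ):
        v = np.asarray(clinical[col], dtype=float)
        out[f"{key}_mean"] = float(v.mean())
        out[f"{key}_sd"] = float(v.std(ddof=1)) if n > 1 else float("nan")
    return out
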