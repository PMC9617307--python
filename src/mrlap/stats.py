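"""Method-comparison statistics for paired LAP measurements.

The harness mirrors a standard agreement analysis between a candidate
estimator and the catheter reference: paired t-tests on the differences,
Pearson correlation with Fisher-z confidence intervals, the "<10 %
difference" consistency rule with a 2x2 subgroup cross-tabulation
(chi-square), rank-sum comparisons of continuous covariates between
consistent and inconsistent patients, and a two-way random-effects
absolute-agreement ICC for observer agreement.

No multiplicity correction is applied; the nominal significance level is
0.05 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    AlignmentError,
    DegenerateTableError,
    MissingDataError,
    UndefinedCorrelationError,
)

__all__ = [
    "PairedComparison",
    "CorrelationResult",
    "Chi2Result",
    "paired_ttest",
    "pearson_ci",
    "consistency_grouping",
    "chi_square_2x2",
    "mann_whitney",
    "icc_agreement",
    "cohort_report",
]


@dataclass(frozen=True)
class PairedComparison:
    """Paired t-test summary on d = x - y."""

    n: int
    mean_diff: float
    ci_low: float
    ci_high: float
    t: float
    p: float
    degenerate: bool = False  # zero-variance differences


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with a Fisher-z 95 % confidence interval."""

    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    p: float
    dof: int
    expected: np.ndarray = field(repr=False, default=None)


def paired_ttest(x, y, *, alpha: float = 0.05) -> PairedComparison:
    """Classical paired t-test on d = x - y with a (1-alpha) CI of the mean.

    Zero-variance differences are reported as a degenerate limit (p = 1 when
    the mean difference is 0, p = 0 otherwise) with ``degenerate=True``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays (paired by subject)")
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 pairs, got {n}")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedComparison(n, 0.0, 0.0, 0.0, 0.0, 1.0, degenerate=True)
        t = float("inf") if mean > 0 else float("-inf")
        return PairedComparison(n, mean, mean, mean, t, 0.0, degenerate=True)
    se = sd / np.sqrt(n)
    t = mean / se
    p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    half = float(sps.t.ppf(1.0 - alpha / 2.0, df=n - 1)) * se
    return PairedComparison(n, mean, mean - half, mean + half, float(t), p)


def pearson_ci(x, y, *, alpha: float = 0.05) -> CorrelationResult:
    """Pearson r with the Fisher-z interval ``tanh(atanh r +/- z/sqrt(n-3))``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 pairs for a Fisher-z interval, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    zcrit = float(sps.norm.ppf(1.0 - alpha / 2.0))
    if abs(r) >= 1.0:
        lo, hi = (r, 1.0) if r > 0 else (-1.0, r)
    else:
        z = np.arctanh(r)
        half = zcrit / np.sqrt(n - 3)
        lo, hi = float(np.tanh(z - half)), float(np.tanh(z + half))
    return CorrelationResult(r=r, ci_low=lo, ci_high=hi, p=float(res.pvalue), n=n)


def consistency_grouping(
    lap_bp, lap_c, strata=None, *, threshold: float = 0.10
) -> tuple[np.ndarray, pd.DataFrame | None]:
    """Label each subject consistent iff ``|lap_bp - lap_c| / lap_c < threshold``.

    The comparison is strict (exactly 10 % is inconsistent) and the reference
    reading is the denominator.  When ``strata`` is given, the labels are
    cross-tabulated against it into a (stratum x {consistent, inconsistent})
    table.
    """
    bp = np.asarray(lap_bp, dtype=float)
    c = np.asarray(lap_c, dtype=float)
    if bp.shape != c.shape or bp.ndim != 1:
        raise ValueError("lap_bp and lap_c must be equal-length 1-D arrays")
    if np.any(c <= 0):
        raise ValueError("reference readings must be positive")
    labels = np.abs(bp - c) / c < threshold
    table = None
    if strata is not None:
        strata = np.asarray(strata)
        if strata.shape != bp.shape:
            raise ValueError("strata must align with the readings")
        table = pd.crosstab(
            pd.Series(strata, name="stratum"),
            pd.Series(np.where(labels, "consistent", "inconsistent"), name="consistency"),
        ).reindex(columns=["consistent", "inconsistent"], fill_value=0)
    return labels, table


def chi_square_2x2(table, *, correction: bool = True) -> Chi2Result:
    """Pearson chi-square on a 2x2 table, optionally Yates-corrected."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or np.any(obs < 0):
        raise ValueError("table must be a 2x2 array of non-negative counts")
    if obs.sum() < 1:
        raise DegenerateTableError("empty table")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise DegenerateTableError("zero marginal in the 2x2 table")
    stat, p, dof, expected = sps.chi2_contingency(obs, correction=correction)
    return Chi2Result(statistic=float(stat), p=float(p), dof=int(dof), expected=expected)


def mann_whitney(a, b) -> tuple[float, float]:
    """Rank-sum U (of the first sample) with tie-corrected normal-approximation p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def icc_agreement(ratings) -> float:
    """Two-way random-effects, absolute-agreement, single-measure ICC.

    ``ratings`` is an (n_subjects x k_raters) grid; the classical
    mean-squares decomposition gives
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)``.
    """
    grid = np.asarray(ratings, dtype=float)
    if grid.ndim != 2:
        raise ValueError("ratings must be a 2-D subject x rater grid")
    n, k = grid.shape
    if k < 2 or n < 5:
        raise ValueError(f"need >= 2 raters and >= 5 subjects, got {k} x {n}")
    if np.any(~np.isfinite(grid)):
        raise MissingDataError("rating grid contains missing values")
    gm = grid.mean()
    row_means = grid.mean(axis=1)
    col_means = grid.mean(axis=0)
    ssr = k * float(((row_means - gm) ** 2).sum())
    ssc = n * float(((col_means - gm) ** 2).sum())
    sst = float(((grid - gm) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0.0:
        # no variance anywhere: perfect (if trivial) agreement
        return 1.0 if np.allclose(grid, grid[0, 0]) else float("nan")
    return float((msr - mse) / denom)


def _paired_block(est: np.ndarray, ref: np.ndarray) -> dict:
    block = {"paired_t": vars(paired_ttest(est, ref))}
    try:
        block["correlation"] = vars(pearson_ci(est, ref))
    except UndefinedCorrelationError as exc:
        block["correlation"] = {"error": str(exc)}
    return block


def cohort_report(cases: pd.DataFrame, estimates: pd.DataFrame) -> dict:
    """Assemble the full method-comparison report for a cohort.

    Parameters
    ----------
    cases : reference table with columns ``case_id``, ``lap_catheter`` and
        optionally ``group``, ``rhythm``, ``p_radial_measured``, ``v_peak``.
    estimates : per-case estimates with ``case_id`` and any of ``lap_eq``,
        ``lap_bp``.

    Returns a JSON-serialisable nested dict with one section per method pair
    (Eq vs catheter, BP vs catheter): paired test, correlation, consistency
    rate, and — when strata are available — the 2x2 disease-composition
    table with its chi-square and rank-sum subgroup comparisons.
    """
    if len(estimates) == 0 or len(cases) == 0:
        raise AlignmentError("empty estimate or reference table")
    merged = cases.merge(estimates, on="case_id", how="inner", suffixes=("", "_est"))
    if len(merged) == 0:
        raise AlignmentError("no overlapping case ids between estimates and reference")

    report: dict = {"n_cases": int(len(merged)), "methods": {}}
    ref_all = merged["lap_catheter"].to_numpy(dtype=float)

    for col, name in (("lap_eq", "Eq_vs_C"), ("lap_bp", "BP_vs_C")):
        if col not in merged.columns:
            continue
        ok = merged[col].notna().to_numpy()
        if ok.sum() < 4:
            report["methods"][name] = {"error": f"only {int(ok.sum())} usable cases"}
            continue
        est = merged.loc[ok, col].to_numpy(dtype=float)
        ref = ref_all[ok]
        section = _paired_block(est, ref)

        labels, _ = consistency_grouping(est, ref)
        section["consistency_rate"] = float(labels.mean())
        if "group" in merged.columns:
            strata = np.where(
                merged.loc[ok, "group"].str.startswith("MVP"), "MVP", "CABG_RHD"
            )
            _, table = consistency_grouping(est, ref, strata)
            section["consistency_table"] = {
                "rows": list(table.index),
                "columns": list(table.columns),
                "counts": table.to_numpy().tolist(),
            }
            if table.shape == (2, 2):
                try:
                    chi = chi_square_2x2(table.to_numpy(), correction=True)
                    section["disease_composition_chi2"] = {
                        "statistic": chi.statistic,
                        "p": chi.p,
                    }
                except DegenerateTableError as exc:
                    section["disease_composition_chi2"] = {"error": str(exc)}
            else:
                section["disease_composition_chi2"] = {
                    "error": "only one stratum present"
                }
            subgroup = {}
            for cov in ("p_radial_measured", "v_peak"):
                if cov in merged.columns:
                    vals = merged.loc[ok, cov].to_numpy(dtype=float)
                    if labels.all() or (~labels).all():
                        subgroup[cov] = {"error": "one consistency group is empty"}
                    else:
                        u, p = mann_whitney(vals[labels], vals[~labels])
                        subgroup[cov] = {"U": u, "p": p}
            if subgroup:
                section["subgroup_rank_sum"] = subgroup
        report["methods"][name] = section
    return report
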