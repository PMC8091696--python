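"""Cohort statistics: outlier exclusion, group tests, correlation, ROC staging.

The analysis chain mirrors a standard group-comparison study: per-rat means
are pooled by histologic stage; values beyond 1.5 interquartile ranges
outside the quartiles are excluded as outliers; stages are compared by
one-way ANOVA with Tukey--Kramer post-hoc pairwise tests; cross-method
agreement is quantified by the Pearson correlation with its t-transform
p-value; and diagnostic performance of a continuous score against a binary
staging is summarized by the nonparametric (rank/Mann--Whitney) AUROC with a
Youden-index optimal cutoff and a Hanley--McNeil normal-approximation
confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .rheology import DEFAULT_RHO

__all__ = [
    "ROCResult",
    "iqr_filter",
    "pearson_test",
    "one_way_anova",
    "tukey_kramer",
    "roc_analysis",
    "study_report",
    "StudyReport",
]


@dataclass(frozen=True)
class ROCResult:
    """Nonparametric ROC summary for one dichotomy."""

    auroc: float
    ci95: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.auroc <= 1.0:
            raise ValueError("AUROC must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "ci95_lo": self.ci95[0],
            "ci95_hi": self.ci95[1],
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


def iqr_filter(values) -> tuple[np.ndarray, np.ndarray]:
    """Split values into (kept, excluded) by the 1.5 x IQR fence rule.

    Quartiles use linear interpolation of order statistics (the exclusion
    set depends on this convention, so it is fixed here). With fewer than 4
    values nothing is excluded (a warning is raised).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        warnings.warn("fewer than 4 values: no outlier exclusion performed")
        return v.copy(), np.array([], dtype=float)
    q1, q3 = np.quantile(v, [0.25, 0.75])  # linear interpolation (default)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = (v >= lo) & (v <= hi)
    return v[keep], v[~keep]


def pearson_test(x, y) -> tuple[float, float]:
    """Sample Pearson correlation and its two-sided t-transform p-value.

    p is computed from ``t = r sqrt(n-2)/sqrt(1-r^2)`` with n-2 degrees of
    freedom. Requires equal lengths, n >= 3 and nonzero variance in both
    variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p-value of a given Pearson r at sample size n (t-transform)."""
    if not -1.0 < r < 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def one_way_anova(groups) -> tuple[float, float]:
    """One-way fixed-effects ANOVA: F statistic and p-value."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    res = sps.f_oneway(*arrays)
    f = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(f):  # identical groups: zero between- and within-variance
        f, p = 0.0, 1.0
    return f, p


def tukey_kramer(groups, alpha: float = 0.05) -> set[tuple[int, int]]:
    """Tukey--Kramer all-pairs comparison at level alpha.

    Pair (i, j) is significant when ``|mean_i - mean_j|`` exceeds
    ``q(alpha, k, df) * sqrt(MSW/2 * (1/n_i + 1/n_j))``, with q the
    studentized-range quantile and MSW the pooled within-group mean square.
    Returns the set of significant index pairs (i < j).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([a.size for a in arrays])
    if np.any(ns < 2):
        raise ValueError("each group needs at least 2 observations")
    means = np.array([a.mean() for a in arrays])
    df = int(ns.sum() - k)
    ssw = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    msw = ssw / df
    if msw == 0:
        return set()
    q_crit = float(sps.studentized_range.ppf(1.0 - alpha, k, df))
    out = set()
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            if abs(means[i] - means[j]) > q_crit * se:
                out.add((i, j))
    return out


def roc_analysis(scores, labels) -> ROCResult:
    """Nonparametric ROC of a continuous score against binary labels.

    AUROC is the rank (Mann--Whitney) estimator with half credit for ties;
    the operating cutoff maximizes the Youden index (sensitivity +
    specificity - 1; ties resolved toward the lower cutoff), classifying
    ``score >= cutoff`` as positive. The 95% CI uses the Hanley--McNeil
    standard error with a normal approximation, clipped to [0, 1].
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and of equal length")
    pos = s[y == 1]
    neg = s[y == 0]
    n_pos, n_neg = pos.size, neg.size
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    # rank estimator with tie correction
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = (greater + 0.5 * ties) / (n_pos * n_neg)

    # Youden-optimal cutoff over candidate thresholds (the observed scores)
    cands = np.unique(s)
    best = None
    for c in cands:  # ascending: first max wins -> lower cutoff on ties
        sens = float(np.mean(pos >= c))
        spec = float(np.mean(neg < c))
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, c, sens, spec)
    _, cutoff, sens, spec = best

    # Hanley-McNeil standard error
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    se = np.sqrt(max(var, 0.0))
    lo = float(np.clip(auc - 1.959963984540054 * se, 0.0, 1.0))
    hi = float(np.clip(auc + 1.959963984540054 * se, 0.0, 1.0))
    return ROCResult(
        auroc=float(auc),
        ci95=(lo, hi),
        cutoff=float(cutoff),
        sensitivity=sens,
        specificity=spec,
        n_pos=n_pos,
        n_neg=n_neg,
    )


# ----------------------------------------------------------------------------
# study assembly


@dataclass
class StudyReport:
    """Full cohort analysis bundle."""

    stage_summary: "object"  # DataFrame: per stage x method x parameter
    anova: dict  # (method, parameter) -> (F, p)
    tukey: dict  # (method, parameter) -> set of significant stage pairs
    pearson: dict  # parameter -> (r, p)
    roc: dict  # dichotomy name -> ROCResult
    combined: "object"  # DataFrame: per-rat combined-fit results

    def to_json_dict(self) -> dict:
        return {
            "anova": {f"{m}_{p}": [f, pv] for (m, p), (f, pv) in self.anova.items()},
            "tukey": {
                f"{m}_{p}": sorted(map(list, pairs)) for (m, p), pairs in self.tukey.items()
            },
            "pearson": {p: list(v) for p, v in self.pearson.items()},
            "roc": {k: v.to_dict() for k, v in self.roc.items()},
        }


_STAGES = ("S0", "S1", "S2", "S3", "S4")


def study_report(rats, rho: float = DEFAULT_RHO, alpha: float = 0.05) -> StudyReport:
    """Assemble the full statistical analysis of a cohort.

    Per-rat replicate means are pooled by stage and IQR-filtered; group
    summaries, ANOVA + Tukey--Kramer across stages, cross-method Pearson
    correlations, and ROC staging of the combined-fit elasticity (S0 vs
    S1-S4 and S0-S1 vs S2-S4) are computed. Deterministic given the cohort.
    """
    import pandas as pd

    from .combined_fit import combined_estimate
    from .cohort import cohort_to_curves

    per_rat = pd.DataFrame(
        {
            "rat_id": [r.rat_id for r in rats],
            "stage": [r.stage for r in rats],
            "swe_mu": [r.mean_swe()[0] for r in rats],
            "swe_eta": [r.mean_swe()[1] for r in rats],
            "dma_mu": [r.mean_dma()[0] for r in rats],
            "dma_eta": [r.mean_dma()[1] for r in rats],
        }
    )

    summary_rows = []
    anova = {}
    tukey = {}
    for method in ("swe", "dma"):
        for param in ("mu", "eta"):
            col = f"{method}_{param}"
            groups = []
            for stage in _STAGES:
                vals = per_rat.loc[per_rat.stage == stage, col].to_numpy()
                kept, excluded = iqr_filter(vals)
                groups.append(kept)
                summary_rows.append(
                    {
                        "stage": stage,
                        "method": method,
                        "parameter": param,
                        "n": kept.size,
                        "n_excluded": excluded.size,
                        "mean": kept.mean() if kept.size else np.nan,
                        "sd": kept.std(ddof=1) if kept.size > 1 else np.nan,
                    }
                )
            anova[(method, param)] = one_way_anova(groups)
            tukey[(method, param)] = tukey_kramer(groups, alpha)

    pearson = {
        "mu": pearson_test(per_rat.swe_mu, per_rat.dma_mu),
        "eta": pearson_test(per_rat.swe_eta, per_rat.dma_eta),
    }

    combined_rows = []
    for rat in rats:
        dma_curve, swe_curve = cohort_to_curves(rat, mode="fast", rho=rho)
        fit = combined_estimate(dma_curve, swe_curve, rho=rho)
        combined_rows.append(
            {
                "rat_id": rat.rat_id,
                "stage": rat.stage,
                "combined_mu_kpa": fit.params.mu / 1e3,
                "combined_eta_pas": fit.params.eta,
                "r2": fit.r2,
                "converged": fit.converged,
            }
        )
    combined = pd.DataFrame(combined_rows)

    stage_num = combined.stage.str.slice(1).astype(int)
    scores = combined.combined_mu_kpa.to_numpy()
    roc = {
        "s0_vs_s1to4": roc_analysis(scores, (stage_num >= 1).astype(int).to_numpy()),
        "s01_vs_s2to4": roc_analysis(scores, (stage_num >= 2).astype(int).to_numpy()),
    }

    return StudyReport(
        stage_summary=pd.DataFrame(summary_rows),
        anova=anova,
        tukey=tukey,
        pearson=pearson,
        roc=roc,
        combined=combined,
    )
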