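"""Group-level statistics for the PET endpoints.

Nonparametric contrasts (Mann–Whitney U, Kruskal–Wallis) with
Benjamini–Hochberg FDR adjustment and Cohen's d effect sizes; a
Shapiro–Wilk gate that decides t-test vs rank test branches in reports;
and the three regression-style analyses of the pipeline: baseline-vs-change
coupling, pooled regional tracer coupling on z-scores, and per-arm
metric-vs-behavior correlation.

Degenerate inputs (zero-variance predictor or response) return flagged
results rather than NaN, so downstream report generation never has to guess
why a fit is empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupTestResult",
    "RegressionResult",
    "shapiro_gate",
    "mwu_test",
    "kruskal_wallis",
    "fdr_adjust",
    "baseline_change_regression",
    "regional_coupling",
    "behavior_correlation",
]


@dataclass
class GroupTestResult:
    comparison: str
    kind: str                  # "KW_H" | "MWU_U" | "T"
    statistic: float
    p: float
    p_adjusted: float | None = None
    method: str = ""
    n: tuple[int, ...] = ()

    def as_dict(self) -> dict:
        return {"comparison": self.comparison, "kind": self.kind,
                "statistic": self.statistic, "p": self.p,
                "p_adjusted": self.p_adjusted, "method": self.method,
                "n": list(self.n)}


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int
    degenerate: bool = False
    note: str = ""
    label: str = ""
    excluded: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"label": self.label, "slope": self.slope,
                "intercept": self.intercept, "r2": self.r2, "p": self.p,
                "n": self.n, "degenerate": self.degenerate, "note": self.note}


def shapiro_gate(values, alpha: float = 0.05) -> str:
    """Shapiro–Wilk branch decision: ``"normal"`` or ``"non_normal"``.

    Used only to choose t-test vs rank-test reporting.  Constant samples
    (test undefined) are labelled non_normal.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if np.ptp(x) == 0:
        return "non_normal"  # degenerate: normality test undefined
    _, p = sps.shapiro(x)
    return "normal" if p >= alpha else "non_normal"


def mwu_test(a, b, alternative: str = "two-sided",
             comparison: str = "") -> GroupTestResult:
    """Mann–Whitney U test.

    Exact enumeration p-value when min(n_a, n_b) <= 8 and there are no ties;
    otherwise the tie-corrected normal approximation (with continuity
    correction).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group in Mann-Whitney test")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return GroupTestResult(comparison=comparison, kind="MWU_U",
                           statistic=float(res.statistic), p=float(res.pvalue),
                           method=f"mann-whitney-{method}",
                           n=(int(a.size), int(b.size)))


def kruskal_wallis(groups, comparison: str = "") -> GroupTestResult:
    """Kruskal–Wallis H (tie-corrected), chi-square p on k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs >=2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group in Kruskal-Wallis test")
    if sum(g.size for g in groups) < 5:
        raise ValueError("Kruskal-Wallis needs total n >= 5")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        raise ValueError("all observations identical: H undefined (all ties)")
    h, p = sps.kruskal(*groups)
    return GroupTestResult(comparison=comparison, kind="KW_H",
                           statistic=float(h), p=float(p),
                           method=f"kruskal-wallis df={len(groups) - 1}",
                           n=tuple(int(g.size) for g in groups))


def fdr_adjust(p_values):
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _ols(x: np.ndarray, y: np.ndarray, label: str = "",
         note: str = "", excluded: list | None = None) -> RegressionResult:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        which = "predictor" if np.ptp(x) == 0 else "response"
        return RegressionResult(slope=0.0, intercept=float(np.mean(y)),
                                r2=0.0, p=1.0, n=int(x.size), degenerate=True,
                                note=f"zero {which} variance; {note}".strip("; "),
                                label=label, excluded=excluded or [])
    fit = sps.linregress(x, y)
    return RegressionResult(slope=float(fit.slope), intercept=float(fit.intercept),
                            r2=float(fit.rvalue**2), p=float(fit.pvalue),
                            n=int(x.size), note=note, label=label,
                            excluded=excluded or [])


def baseline_change_regression(baseline: pd.Series,
                               followup: pd.Series,
                               label: str = "") -> RegressionResult:
    """OLS of percentage change on baseline, paired by subject.

    response = 100 * (followup - baseline) / baseline.  Subjects missing
    either timepoint are excluded listwise and listed in the result.
    """
    joined = pd.concat({"baseline": baseline, "followup": followup}, axis=1)
    excluded = sorted(joined.index[joined.isna().any(axis=1)])
    joined = joined.dropna()
    if len(joined) < 3:
        raise ValueError(f"need >=3 paired subjects, got {len(joined)}")
    if (joined["baseline"] <= 0).any():
        raise ValueError("non-positive baseline value")
    change = 100.0 * (joined["followup"] - joined["baseline"]) / joined["baseline"]
    return _ols(joined["baseline"].to_numpy(), change.to_numpy(), label=label,
                excluded=excluded)


def regional_coupling(tspo_z: pd.DataFrame, abeta_z: pd.DataFrame,
                      label: str = "") -> RegressionResult:
    """Pooled OLS of TSPO z on amyloid z over all (subject, VOI) points.

    Inputs are long z-score tables (one row per subject/VOI measurement) or
    any frames with ``subject_id``, ``voi``, ``value`` columns; points are
    matched on (subject_id, voi).  Each subject contributes many regional
    points, so the fit is flagged descriptive (non-independent points).
    """
    cols = ["subject_id", "voi", "value"]
    merged = tspo_z[cols].merge(abeta_z[cols], on=["subject_id", "voi"],
                                suffixes=("_tspo", "_abeta")).dropna()
    if len(merged) < 3:
        raise ValueError(f"need >=3 matched (subject, VOI) points, got {len(merged)}")
    return _ols(merged["value_abeta"].to_numpy(), merged["value_tspo"].to_numpy(),
                label=label, note="descriptive (non-independent points)")


def behavior_correlation(metric: pd.Series, behavior: pd.DataFrame,
                         stratify_by: str = "arm",
                         min_n: int = 3) -> dict[str, RegressionResult]:
    """Per-stratum OLS of quadrant time on a subject-level PET metric.

    ``metric`` is indexed by subject_id (e.g. cortical DI PC1 or SUVR);
    ``behavior`` has subject_id / quadrant_time / arm / genotype columns.
    Strata with fewer than ``min_n`` subjects are skipped with a flagged
    placeholder.  No cross-stratum slope comparison is performed.
    """
    df = behavior.set_index("subject_id").join(metric.rename("metric"), how="inner")
    out: dict[str, RegressionResult] = {}
    for stratum, sub in df.groupby(stratify_by, sort=True):
        sub = sub.dropna(subset=["metric", "quadrant_time"])
        if len(sub) < min_n:
            out[str(stratum)] = RegressionResult(
                slope=np.nan, intercept=np.nan, r2=np.nan, p=np.nan,
                n=len(sub), degenerate=True,
                note=f"stratum skipped: n={len(sub)} < {min_n}",
                label=str(stratum))
            continue
        out[str(stratum)] = _ols(sub["metric"].to_numpy(),
                                 sub["quadrant_time"].to_numpy(),
                                 label=str(stratum))
    return out
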