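"""Repeated-measures comparison and correlation layer.

The analysis mirrors common practice for small within-subject designs:
normality of within-subject difference scores is checked per feature and
factor (Shapiro-Wilk at alpha = 0.05); when the assumption holds the omnibus
is a repeated-measures ANOVA with paired-t post-hoc contrasts, otherwise the
Friedman test with Wilcoxon signed-rank pairwise contrasts.  HRV-vs-load
associations use Spearman rank correlation within each physical-load
stratum, pooling the cognitive-load levels within subjects.  Raw p-values
are reported by default (the study convention); Holm correction is
available behind a flag.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

ALPHA_NORMALITY = 0.05
#: Wilcoxon switches from the exact null distribution to the normal
#: approximation at this sample size
WILCOXON_EXACT_MAX_N = 25


@dataclass(frozen=True)
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    n: int
    contrast: str
    feature: str = ""

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if self.n <= 0:
            raise ValueError("n must be positive")


def _subject_level_matrix(table: pd.DataFrame, feature: str, factor: str
                          ) -> pd.DataFrame:
    """Pivot to subject x factor-level, averaging over the other factor.

    Subjects missing any level are dropped listwise (with a logged count),
    keeping the design balanced as the paired tests require.
    """
    col = {"CL": "cl_level", "PL": "pl_level"}[factor]
    wide = table.pivot_table(index="subject", columns=col, values=feature,
                             aggfunc="mean")
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        logger.info("dropped %d incomplete subjects for %s x %s", dropped, feature, factor)
    return complete


def friedman_test(*samples: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square with tie correction, valid for k >= 2 levels.

    For k >= 3 this defers to scipy; for k = 2 (where scipy refuses) the
    statistic is computed from within-subject ranks directly — in that case
    it is a monotone function of the sign-test count.
    """
    k = len(samples)
    if k >= 3:
        res = sps.friedmanchisquare(*samples)
        return float(res.statistic), float(res.pvalue)
    if k != 2:
        raise ValueError("need at least 2 levels")
    mat = np.column_stack(samples)
    n = mat.shape[0]
    ranks = np.apply_along_axis(sps.rankdata, 1, mat)
    rank_sums = ranks.sum(axis=0)
    chi2 = (12.0 * np.sum(rank_sums ** 2) / (n * k * (k + 1))
            - 3.0 * n * (k + 1))
    ties = 0.0
    for row in mat:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts ** 3 - counts)
    correction = 1.0 - ties / (n * k * (k ** 2 - 1))
    if correction <= 0:
        return 0.0, 1.0  # every subject tied across both levels
    chi2 /= correction
    return float(chi2), float(sps.chi2.sf(chi2, k - 1))


def _wilcoxon(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    d = x - y
    d = d[d != 0]  # signed-rank convention: zeros dropped
    if len(d) == 0:
        return 0.0, 1.0
    method = "exact" if len(d) <= WILCOXON_EXACT_MAX_N else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_repeated(table: pd.DataFrame, feature: str, factor: str,
                     holm: bool = False) -> list[StatResult]:
    """Omnibus + all pairwise contrasts of ``feature`` across ``factor`` levels.

    ``table`` holds one row per subject x condition with columns ``subject``,
    ``cl_level``, ``pl_level`` and the feature; rows sharing a factor level
    (the other factor's levels) are averaged within subject first.  The
    parametric path (rmANOVA + paired t) is taken only when every pairwise
    difference passes Shapiro-Wilk; otherwise Friedman + Wilcoxon.
    """
    wide = _subject_level_matrix(table, feature, factor)
    levels = list(wide.columns)
    if len(levels) < 2:
        raise ValueError("need at least 2 factor levels")
    if len(wide) < 3:
        raise ValueError("need at least 3 complete subjects")
    n = len(wide)
    arrays = {lv: wide[lv].to_numpy() for lv in levels}
    pairs = list(itertools.combinations(levels, 2))

    normal = True
    for a, b in pairs:
        d = arrays[a] - arrays[b]
        if np.ptp(d) == 0:
            normal = False  # degenerate differences: use the rank tests
            break
        if sps.shapiro(d).pvalue < ALPHA_NORMALITY:
            normal = False
            break
    logger.info("assumption gate for %s x %s: %s path", feature, factor,
                "parametric" if normal else "nonparametric")

    results: list[StatResult] = []
    if normal:
        from statsmodels.stats.anova import AnovaRM
        long = wide.reset_index().melt(id_vars="subject", var_name="level",
                                       value_name="value")
        fit = AnovaRM(long, depvar="value", subject="subject",
                      within=["level"]).fit()
        row = fit.anova_table.iloc[0]
        results.append(StatResult("rmANOVA", float(row["F Value"]),
                                  float(row["Pr > F"]), n,
                                  f"{factor} omnibus", feature))
        for a, b in pairs:
            t = sps.ttest_rel(arrays[a], arrays[b])
            results.append(StatResult("paired t", float(t.statistic),
                                      float(t.pvalue), n, f"{a} vs {b}", feature))
    else:
        cols = [arrays[lv] for lv in levels]
        if np.all(np.ptp(np.column_stack(cols), axis=1) == 0):
            stat_val, p = 0.0, 1.0  # every subject identical across levels
        else:
            stat_val, p = friedman_test(*cols)
        results.append(StatResult("Friedman", float(stat_val), float(p), n,
                                  f"{factor} omnibus", feature))
        for a, b in pairs:
            w, p = _wilcoxon(arrays[a], arrays[b])
            results.append(StatResult("Wilcoxon signed-rank", w, p, n,
                                      f"{a} vs {b}", feature))
    if holm:
        results = _holm_adjust(results)
    return results


def _holm_adjust(results: list[StatResult]) -> list[StatResult]:
    """Holm step-down correction over the pairwise contrasts (omnibus untouched)."""
    pairwise = [r for r in results if "omnibus" not in r.contrast]
    m = len(pairwise)
    order = np.argsort([r.p_value for r in pairwise])
    adj = {}
    running = 0.0
    for rank, idx in enumerate(order):
        p = min(1.0, (m - rank) * pairwise[idx].p_value)
        running = max(running, p)
        adj[id(pairwise[idx])] = running
    return [r if "omnibus" in r.contrast else
            StatResult(r.test_name, r.statistic, adj[id(r)], r.n, r.contrast, r.feature)
            for r in results]


def correlate_load(table: pd.DataFrame, hrv_features: list[str],
                   load_measures: list[str]) -> pd.DataFrame:
    """Spearman rho between HRV features and load measures per PL stratum.

    Within each physical-load level the three cognitive-load levels are
    pooled within subjects (one observation per subject x CL cell), giving
    one correlation matrix per stratum.  Repeated subject contributions are
    pooled, not modeled.  Constant columns yield a NaN rho marker.
    """
    rows = []
    for pl, sub in table.groupby("pl_level"):
        for feat in hrv_features:
            for meas in load_measures:
                pair = sub[[feat, meas]].dropna()
                if len(pair) < 5:
                    raise ValueError(
                        f"need >= 5 paired observations, got {len(pair)} "
                        f"for {feat} vs {meas} at PL={pl}")
                x, y = pair[feat].to_numpy(), pair[meas].to_numpy()
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    rho, p = float("nan"), float("nan")
                else:
                    rho, p = sps.spearmanr(x, y)
                rows.append({"pl_level": pl, "feature": feat, "measure": meas,
                             "rho": float(rho), "p_value": float(p), "n": len(pair)})
    return pd.DataFrame(rows)


HRV_FEATURES = ["meanHR", "SDNN", "NN50", "pNN50", "RMSSD",
                "aVLF", "aLF", "aHF", "aTotal", "LF_HF", "nLF", "nHF"]
BEHAVIOR_FEATURES = ["MRT", "SDRT", "CNR", "MNR", "WNR", "TLX_total"]


@dataclass
class StudyReport:
    """Three-stage analysis mirroring the study's results organization.

    Stage 1: subjective workload and task performance across CL and PL.
    Stage 2: HRV features across PL within each CL level.
    Stage 3: Spearman correlations of HRV with TLX total and mean RT per PL.
    """

    workload_performance: pd.DataFrame
    hrv_by_pl: pd.DataFrame
    correlations: pd.DataFrame
    header: str = ("Correlations pool the three cognitive-load levels within "
                   "each physical-load stratum; repeated subject contributions "
                   "are pooled, not modeled.")


def _results_frame(results: list[StatResult], **extra) -> pd.DataFrame:
    return pd.DataFrame([{**extra, "feature": r.feature, "test": r.test_name,
                          "contrast": r.contrast, "statistic": r.statistic,
                          "p_value": r.p_value, "n": r.n} for r in results])


def run_study_analysis(table: pd.DataFrame, holm: bool = False) -> StudyReport:
    """Execute the three-stage analysis on a subject x condition feature table.

    ``table`` must carry one row per subject x condition with the HRV,
    performance and TLX columns produced by the pipeline feature stage.
    """
    required = {"subject", "cl_level", "pl_level"}
    if not required <= set(table.columns):
        raise ValueError(f"stage inputs missing: feature table needs columns {required}")

    stage1 = []
    behav = [f for f in BEHAVIOR_FEATURES if f in table.columns]
    if not behav:
        raise ValueError("stage 1 inputs missing: no workload/performance columns")
    for feat in behav:
        for factor in ("CL", "PL"):
            stage1.append(_results_frame(
                compare_repeated(table, feat, factor, holm=holm), factor=factor))

    stage2 = []
    hrv_cols = [f for f in HRV_FEATURES if f in table.columns]
    if not hrv_cols:
        raise ValueError("stage 2 inputs missing: no HRV columns")
    for cl, sub in table.groupby("cl_level"):
        for feat in hrv_cols:
            stage2.append(_results_frame(
                compare_repeated(sub, feat, "PL", holm=holm), cl_level=cl))

    load_measures = [m for m in ("TLX_total", "MRT") if m in table.columns]
    if not load_measures:
        raise ValueError("stage 3 inputs missing: no load-measure columns")
    stage3 = correlate_load(table, hrv_cols, load_measures)

    return StudyReport(workload_performance=pd.concat(stage1, ignore_index=True),
                       hrv_by_pl=pd.concat(stage2, ignore_index=True),
                       correlations=stage3)
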