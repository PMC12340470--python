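"""Summary statistics, hypothesis tests and effect sizes.

Cohen's d here follows the summary-statistics convention used in
cross-study comparisons of segmentation variability: when a study reports
median (IQR) instead of mean ± SD, the median substitutes for the mean and
σ ≈ IQR/1.35 (normal-theory quartile spread).  The pooled SD is the
unweighted two-group root mean square sqrt((σ1² + σ2²)/2); sample sizes do
not enter.  A fixture of published summary statistics ships with the
package so the full cross-study effect-size table is reproducible offline.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

IQR_TO_SD = 1.35          # IQR width of a normal is 1.349 σ; 1.35 by convention
DEFAULT_N_COMPARISONS = 3  # the three main manual-method comparisons


class StatsError(ValueError):
    pass


@dataclass
class MetricSummary:
    median: float
    iqr_low: float
    iqr_high: float
    n: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.iqr_low <= self.median <= self.iqr_high:
            raise StatsError("quartiles must bracket the median")
        if self.n < 1:
            raise StatsError("n must be >= 1")

    @property
    def iqr_width(self) -> float:
        return self.iqr_high - self.iqr_low

    def __str__(self) -> str:
        return (f"{self.label}: {self.median:.2f} "
                f"({self.iqr_low:.2f}-{self.iqr_high:.2f}), n={self.n}")


@dataclass
class EffectSize:
    d: float
    group1: tuple[float, float]    # (center, sd)
    group2: tuple[float, float]
    sd_source: str = "reported_sd"  # or "iqr_approx"

    @property
    def magnitude(self) -> str:
        return classify_effect(self.d)


def sigma_from_iqr(iqr_width: float) -> float:
    """SD estimate from an interquartile range width, σ ≈ IQR/1.35."""
    if iqr_width < 0:
        raise StatsError("IQR width must be >= 0")
    return iqr_width / IQR_TO_SD


def cohens_d(center1: float, sd1: float, center2: float, sd2: float,
             sd_source: str = "reported_sd") -> EffectSize:
    """Standardized difference (center1 − center2) / pooled SD.

    Pooled SD = sqrt((sd1² + sd2²)/2).  Negative d: group 1 is lower.
    """
    if sd1 < 0 or sd2 < 0:
        raise StatsError("standard deviations must be >= 0")
    pooled = np.sqrt((sd1 ** 2 + sd2 ** 2) / 2.0)
    if pooled == 0:
        if center1 == center2:
            return EffectSize(0.0, (center1, sd1), (center2, sd2), sd_source)
        raise StatsError("zero pooled SD with unequal centers: d undefined")
    return EffectSize(float((center1 - center2) / pooled),
                      (center1, sd1), (center2, sd2), sd_source)


def classify_effect(d: float) -> str:
    """|d| thresholds 0.2 / 0.5 / 0.8 -> negligible/small/moderate/large."""
    if not np.isfinite(d):
        raise StatsError("d must be finite")
    a = abs(d)
    if a < 0.2:
        return "negligible"
    if a < 0.5:
        return "small"
    if a < 0.8:
        return "moderate"
    return "large"


def summarize(values, label: str = "") -> MetricSummary:
    """Median and linearly interpolated quartiles (type-7) with n."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise StatsError("cannot summarize an empty sample")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    return MetricSummary(float(med), float(q1), float(q3), int(arr.size),
                         label)


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    p_adjusted: float
    n_comparisons: int
    shapiro_p: tuple[float | None, float | None]
    normal: bool


def compare_groups(x, y, paired: bool = False,
                   n_comparisons: int = DEFAULT_N_COMPARISONS
                   ) -> GroupComparison:
    """Wilcoxon signed-rank (paired) or rank-sum test with a Shapiro–Wilk
    normality note and Bonferroni adjustment."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise StatsError("need at least 3 observations per group")
    if paired and len(x) != len(y):
        raise StatsError("paired comparison needs equal lengths")

    def _shapiro(v):
        if len(np.unique(v)) < 3:
            return None
        return float(sps.shapiro(v).pvalue)

    sw = (_shapiro(x), _shapiro(y))
    normal = all(p is not None and p > 0.05 for p in sw)
    if paired:
        diff = x - y
        if np.allclose(diff, 0.0):
            stat, p = 0.0, 1.0
        else:
            res = sps.wilcoxon(x, y, zero_method="zsplit")
            stat, p = float(res.statistic), float(res.pvalue)
        test = "wilcoxon_signed_rank"
    else:
        res = sps.ranksums(x, y)
        stat, p = float(res.statistic), float(res.pvalue)
        test = "wilcoxon_rank_sum"
    return GroupComparison(test, stat, p, min(1.0, p * n_comparisons),
                           n_comparisons, sw, normal)


# ---------------------------------------------------------------------------
# Published summary-statistics fixture and the cross-study d table
# ---------------------------------------------------------------------------

# comparison key in the fixture -> present-study row that anchors it
_PRESENT_ANCHOR = {
    "manual_vs_semiauto": "manual_vs_semiauto",
    "inter_manual": "inter_manual_softssm",
    "inter_semiauto": "inter_semiauto",
}


def load_paper_summaries() -> pd.DataFrame:
    """Published per-study summary statistics (medians/IQRs or mean±SD)."""
    with resources.files("prosegvar.data").joinpath(
            "paper_summaries.csv").open() as fh:
        df = pd.read_csv(fh, keep_default_na=False)
    for col in ("center", "sd", "iqr_low", "iqr_high"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def cross_study_effect_sizes(summaries: pd.DataFrame | None = None
                             ) -> pd.DataFrame:
    """Cohen's d of the present study's summaries against each published
    study, in fixture order.

    Present-study rows contribute median + σ-from-IQR; literature rows
    contribute mean ± SD directly.
    """
    df = load_paper_summaries() if summaries is None else summaries
    if "sd" not in df.columns:
        raise StatsError("fixture is missing the sd column")
    present = df[df["study"] == "present"].set_index("comparison")
    rows = []
    for _, lit in df[df["study"] != "present"].iterrows():
        anchor_key = _PRESENT_ANCHOR.get(lit["comparison"])
        if anchor_key is None or anchor_key not in present.index:
            continue
        anchor = present.loc[anchor_key]
        sigma = sigma_from_iqr(float(anchor["iqr_high"])
                               - float(anchor["iqr_low"]))
        if not np.isfinite(lit["sd"]):
            raise StatsError(f"missing SD for study {lit['study']!r}")
        eff = cohens_d(float(anchor["center"]), sigma,
                       float(lit["center"]), float(lit["sd"]),
                       sd_source="iqr_approx")
        rows.append({
            "study": lit["study"],
            "comparison": lit["comparison"],
            "present_center": float(anchor["center"]),
            "present_sigma": sigma,
            "study_mean": float(lit["center"]),
            "study_sd": float(lit["sd"]),
            "d": eff.d,
            "d_rounded": round(eff.d, 2),
            "classification": eff.magnitude,
        })
    if not rows:
        raise StatsError("no cross-study pairs found in fixture")
    return pd.DataFrame(rows)
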