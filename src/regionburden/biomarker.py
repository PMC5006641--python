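"""IHC biomarker statistics, two-group power calculation, and ddPCR QC.

Nuclear staining is scored per nucleus on a 0/1+/2+/3+ intensity scale and
aggregated to per-case bin percentages; the biomarker readout is the percent
of nuclei at 3+ (strong staining).  Group differences use one-way ANOVA with
Tukey HSD; discrimination uses a binomial GLM (logistic regression) of the
case label on percent-3+ with an ROC curve and AUC.  The two-group sample
size uses the normal-approximation formula with unpooled variances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from statsmodels.stats.multicomp import pairwise_tukeyhsd

INTENSITY_BINS = (0, 1, 2, 3)
PCT_COLUMNS = ["pct0", "pct1", "pct2", "pct3"]

DDPCR_MIN_DROPLETS = 7000


def aggregate_nuclear_scores(intensities, case_id: str = "", group: str = "") -> pd.Series:
    """Aggregate per-nucleus intensity calls (values 0..3) to bin percentages.

    Returns a Series with case_id, group and pct0..pct3 (each bin is
    100 * count / total, so the four percentages sum to exactly 100).
    """
    calls = np.asarray(intensities, dtype=np.int64)
    if calls.size == 0:
        raise ValueError("no nuclei to aggregate")
    if calls.min() < 0 or calls.max() > 3:
        raise ValueError("intensity calls must be in 0..3")
    counts = np.bincount(calls, minlength=4)[:4]
    pct = 100.0 * counts / calls.size
    return pd.Series(
        {"case_id": case_id, "group": group, **dict(zip(PCT_COLUMNS, pct))}
    )


@dataclass
class GroupComparisonResult:
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, lower, upper, reject
    groups: list[str]

    def pairwise_p(self, group1: str, group2: str) -> float:
        t = self.tukey
        row = t[((t["group1"] == group1) & (t["group2"] == group2)) | ((t["group1"] == group2) & (t["group2"] == group1))]
        if len(row) == 0:
            raise KeyError(f"no contrast {group1} vs {group2}")
        return float(row["p_adj"].iloc[0])


def group_comparison(
    scores: pd.DataFrame, value_col: str = "pct3", group_col: str = "group"
) -> GroupComparisonResult:
    """One-way ANOVA on the value column followed by Tukey HSD contrasts."""
    groups = [str(g) for g in pd.unique(scores[group_col])]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [scores.loc[scores[group_col] == g, value_col].to_numpy(dtype=float) for g in groups]
    if min(len(a) for a in arrays) < 2:
        raise ValueError("need at least two cases per group")
    values = np.concatenate(arrays)
    if np.ptp(values) == 0:
        raise ValueError("degenerate data: zero variance overall")
    f_stat, p = stats.f_oneway(*arrays)
    res = pairwise_tukeyhsd(values, np.repeat(groups, [len(a) for a in arrays]))
    table = pd.DataFrame(res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]])
    table = table.rename(columns={"p-adj": "p_adj"})
    # the summary table rounds; use the unrounded adjusted p-values
    table["p_adj"] = res.pvalues
    return GroupComparisonResult(float(f_stat), float(p), table, groups)


@dataclass
class LogisticRocResult:
    params: pd.Series          # intercept and slope of the logistic fit
    pvalues: pd.Series
    auc: float
    roc: pd.DataFrame          # fpr, tpr, threshold
    separation: bool           # complete separation flag (fit is degenerate)
    n_cases: int
    n_controls: int

    def summary(self) -> str:
        lines = [
            "Logistic biomarker model (label ~ percent 3+ nuclei)",
            f"  n: {self.n_cases} positive / {self.n_controls} negative",
            f"  intercept: {self.params['const']: .4g}   slope: {self.params['pct3']: .4g}"
            + ("   [complete separation]" if self.separation else ""),
            f"  slope p-value: {self.pvalues['pct3']:.3g}",
            f"  ROC AUC: {self.auc:.3f}",
        ]
        return "\n".join(lines)


def rank_auc(values, labels) -> float:
    """AUC as the Mann-Whitney rank statistic (ties count 1/2)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    u = stats.mannwhitneyu(values[labels], values[~labels], alternative="two-sided").statistic
    return float(u / (n1 * n0))


def logistic_roc(values, labels) -> LogisticRocResult:
    """Fit label ~ value by maximum-likelihood logistic regression, with ROC.

    ``labels`` is boolean (True = positive class, e.g. HGSOC vs benign).
    Complete separation is flagged (the MLE diverges there) and the ROC/AUC
    are still defined — they depend only on the ordering of the values.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    X = sm.add_constant(pd.DataFrame({"pct3": values}))
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(labels.astype(int), X).fit(disp=0, maxiter=200)
            params, pvalues = fit.params, fit.pvalues
            fitted = fit.predict(X)
            if np.all((fitted > 0.999) == labels) and np.all((fitted < 0.001) == ~labels):
                separation = True
        except Exception:
            separation = True
            params = pd.Series({"const": np.nan, "pct3": np.nan})
            pvalues = pd.Series({"const": np.nan, "pct3": np.nan})
    fpr, tpr, thresholds = roc_curve(labels.astype(int), values)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return LogisticRocResult(
        params=params,
        pvalues=pvalues,
        auc=float(_trapezoid_auc(fpr, tpr)),
        roc=roc,
        separation=separation,
        n_cases=n1,
        n_controls=n0,
    )


def sample_size_two_groups(
    mean1: float, sd1: float, mean2: float, sd2: float,
    power: float = 0.90, alpha_two_sided: float = 0.05,
) -> int:
    """Per-group n for a two-sample comparison of means (normal approximation).

        n = (z_{1-alpha/2} + z_power)^2 * (sd1^2 + sd2^2) / delta^2

    with unpooled variances, rounded to the nearest integer.  With the
    benign/HGSOC staining parameters (3 +/- 4 vs 14 +/- 10, 90% power, 5%
    two-sided alpha) this gives ten cases per group.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if not (0 < power < 1):
        raise ValueError("power must be in (0, 1)")
    delta = mean2 - mean1
    if delta == 0:
        raise ValueError("means are equal: effect size is zero")
    z_alpha = stats.norm.ppf(1 - alpha_two_sided / 2)
    z_power = stats.norm.ppf(power)
    n = (z_alpha + z_power) ** 2 * (sd1**2 + sd2**2) / delta**2
    return int(np.floor(n + 0.5))


def ddpcr_fraction(wells: pd.DataFrame, min_droplets: int = DDPCR_MIN_DROPLETS) -> pd.DataFrame:
    """Per-sample mutant allele fraction from droplet counts with QC.

    Wells with total droplets below ``min_droplets`` fail QC and are excluded;
    the fraction is pooled mutant / (mutant + wildtype) over passing wells.
    Samples with no passing wells get a NaN fraction.

    ``wells`` columns: sample_id, mutant, wildtype, total.
    """
    for col in ("sample_id", "mutant", "wildtype", "total"):
        if col not in wells.columns:
            raise ValueError(f"wells table missing column {col!r}")
    if (wells[["mutant", "wildtype", "total"]] < 0).any().any():
        raise ValueError("droplet counts must be >= 0")
    if (wells["total"] < wells["mutant"] + wells["wildtype"]).any():
        raise ValueError("total droplets must be >= mutant + wildtype")
    wells = wells.copy()
    wells["qc_pass"] = wells["total"] >= min_droplets
    rows = []
    for sample, sub in wells.groupby("sample_id", sort=True):
        passing = sub[sub["qc_pass"]]
        mut = int(passing["mutant"].sum())
        wt = int(passing["wildtype"].sum())
        frac = mut / (mut + wt) if (mut + wt) > 0 and len(passing) else np.nan
        rows.append((sample, len(sub), len(passing), mut, wt, frac))
    return pd.DataFrame(
        rows, columns=["sample_id", "n_wells", "n_pass", "mutant", "wildtype", "mutant_fraction"]
    )


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class IHCBiomarker:
    """Biomarker analysis of per-case IHC intensity scores.

    Parameters
    ----------
    scores : DataFrame with case_id, group and pct0..pct3 columns
    positive, negative : group labels defining the binary contrast for the
        logistic model and ROC (default hgsoc vs benign)
    value_col : biomarker readout column (percent of 3+ nuclei)
    """

    def __init__(
        self,
        scores: pd.DataFrame,
        positive: str = "hgsoc",
        negative: str = "benign",
        value_col: str = "pct3",
    ) -> None:
        sums = scores[PCT_COLUMNS].sum(axis=1)
        if not np.allclose(sums, 100.0, atol=1e-9):
            raise ValueError("intensity-bin percentages must sum to 100 per case")
        self.scores = scores
        self.positive = positive
        self.negative = negative
        self.value_col = value_col

    @classmethod
    def from_dataframe(cls, scores: pd.DataFrame, **kwargs) -> "IHCBiomarker":
        return cls(scores, **kwargs)

    def fit(self) -> "IHCBiomarkerResults":
        anova = group_comparison(self.scores, self.value_col)
        binary = self.scores[self.scores["group"].isin([self.positive, self.negative])]
        logistic = logistic_roc(
            binary[self.value_col].to_numpy(),
            (binary["group"] == self.positive).to_numpy(),
        )
        return IHCBiomarkerResults(anova, logistic, self)


class IHCBiomarkerResults:
    def __init__(self, anova: GroupComparisonResult, logistic: LogisticRocResult, model: IHCBiomarker) -> None:
        self.anova = anova
        self.logistic = logistic
        self.model = model
        self.auc = logistic.auc

    def summary(self) -> str:
        lines = [
            "IHC biomarker analysis (percent of nuclei at 3+)",
            "================================================",
            f"groups: {', '.join(self.anova.groups)}",
            f"one-way ANOVA: F = {self.anova.f_statistic:.4g}, p = {self.anova.p_value:.3g}",
            "Tukey HSD contrasts:",
            self.anova.tukey.to_string(index=False),
            "",
            self.logistic.summary(),
        ]
        return "\n".join(lines)
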