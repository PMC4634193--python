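"""Statistical battery with automatic test selection.

Group comparisons follow a fixed protocol: each sample is first screened for
normality with a one-sample Kolmogorov-Smirnov test against a Gaussian with
the sample's own mean and SD (no Lilliefors correction, which makes the
screen conservative — it accepts Gaussianity too readily).  Unpaired groups
are then compared with Welch's t test if both pass the screen, otherwise with
Mann-Whitney; paired data always use the Wilcoxon signed-rank test.  Pooled
distributions are compared with the two-sample KS test.  All tests are
two-sided; no multiple-testing correction is applied.  Every auto-selected
comparison records its selection path (normality verdicts and chosen test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

ALPHA_NORMALITY = 0.05


@dataclass
class StatResult:
    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    selection_path: list[str] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p value {self.p_value} outside [0, 1]")

    @property
    def significant_05(self) -> bool:
        return self.p_value < 0.05

    @property
    def significant_01(self) -> bool:
        return self.p_value < 0.01

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "n": list(self.n),
            "selection_path": self.selection_path,
            "summary": self.summary,
        }


@dataclass
class NormalityVerdict:
    gaussian: bool
    statistic: float
    p_value: float
    flags: list[str] = field(default_factory=list)


def normality_check(sample, alpha: float = ALPHA_NORMALITY) -> NormalityVerdict:
    """One-sample KS distance against N(sample mean, sample sd); n >= 4.

    A zero-variance sample is non-Gaussian by fiat (flagged).
    """
    x = np.asarray(sample, float)
    if len(x) < 4:
        raise ValueError("normality screen needs n >= 4")
    sd = x.std(ddof=1)
    if sd == 0:
        return NormalityVerdict(False, np.nan, np.nan, flags=["zero_variance"])
    stat, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return NormalityVerdict(bool(p >= alpha), float(stat), float(p))


def summarize(sample, style: str = "mean_sem") -> dict:
    """mean ± SEM or median with quartiles, with n attached."""
    x = np.asarray(sample, float)
    if style == "mean_sem":
        if len(x) < 2:
            raise ValueError("SEM requires n >= 2")
        return {
            "mean": float(x.mean()),
            "sem": float(x.std(ddof=1) / np.sqrt(len(x))),
            "n": len(x),
        }
    if style == "median_quartiles":
        if len(x) < 1:
            raise ValueError("empty sample")
        q25, med, q75 = np.percentile(x, [25, 50, 75])
        return {"median": float(med), "q25": float(q25), "q75": float(q75), "n": len(x)}
    raise ValueError(f"unknown summary style {style!r}")


def compare_groups(a, b, paired: bool = False) -> StatResult:
    """Auto-selected two-group comparison (two-sided).

    Unpaired: Welch's t if both normality screens pass, else Mann-Whitney.
    Paired: Wilcoxon signed-rank (requires equal lengths).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal-length samples")
        res = sps.wilcoxon(a, b)
        return StatResult(
            test="wilcoxon_signed_rank",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            n=(len(a), len(b)),
            selection_path=["paired -> wilcoxon_signed_rank"],
            summary={"a": summarize(a, "median_quartiles"), "b": summarize(b, "median_quartiles")},
        )
    va = normality_check(a)
    vb = normality_check(b)
    path = [
        f"normality(a): {'gaussian' if va.gaussian else 'non-gaussian'} (p={va.p_value:.3g})",
        f"normality(b): {'gaussian' if vb.gaussian else 'non-gaussian'} (p={vb.p_value:.3g})",
    ]
    if va.gaussian and vb.gaussian:
        res = sps.ttest_ind(a, b, equal_var=False)
        path.append("both gaussian -> welch_t")
        return StatResult(
            test="welch_t",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            n=(len(a), len(b)),
            selection_path=path,
            summary={"a": summarize(a, "mean_sem"), "b": summarize(b, "mean_sem")},
        )
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    path.append("non-gaussian -> mann_whitney")
    return StatResult(
        test="mann_whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(len(a), len(b)),
        selection_path=path,
        summary={"a": summarize(a, "median_quartiles"), "b": summarize(b, "median_quartiles")},
    )


def mann_whitney(a, b) -> StatResult:
    """Mann-Whitney U, two-sided; exact null when samples are small and tie-free."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and len(np.unique(np.r_[a, b])) == len(a) + len(b)) else "auto"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return StatResult(
        test="mann_whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(len(a), len(b)),
        selection_path=[f"method={method}"],
    )


def ks_two_sample(a, b) -> StatResult:
    """Two-sample KS: max ECDF distance D with asymptotic p."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("two-sample KS needs n >= 2 in both samples")
    res = sps.ks_2samp(a, b, method="asymp")
    return StatResult(
        test="ks_two_sample",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(len(a), len(b)),
    )


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    slope: float
    intercept: float
    n: int


def correlate(x, y) -> CorrelationResult:
    """Pearson r with the fitted regression line."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("correlate needs equal-length samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    lr = sps.linregress(x, y)
    return CorrelationResult(
        r=float(lr.rvalue),
        p_value=float(lr.pvalue),
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        n=len(x),
    )
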