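"""Cross-species evolutionary-rate statistics.

Given per-species ceWGT Ks peaks, this module computes pairwise percent
rate differences (slower species in the denominator), summaries for the
P1R/P2R groups (mean, sample SD, coefficient of variation), a Welch
two-sample t-test between groups, and the Pearson correlation of peak
height with the number of polyploidy rounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from paleoks.formats import SpeciesMeta
from paleoks.peaks import PeakModel


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float

    @property
    def cv(self) -> float:
        """Coefficient of variation sd/mean."""
        return self.sd / self.mean


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: float
    method: str


def rate_difference(p_fast: float, p_slow: float) -> float:
    """Percent rate difference 100 * (p_fast - p_slow) / p_slow.

    The slower (reference) species sits in the denominator; rounding is a
    display concern, the full value is returned.
    """
    if p_fast <= 0 or p_slow <= 0:
        raise StatsError(f"peaks must be positive, got {p_fast}, {p_slow}")
    return 100.0 * (p_fast - p_slow) / p_slow


def group_summary(peaks, group: str) -> GroupSummary:
    """Mean, sample SD (n-1 denominator) and CV of a group's peaks."""
    x = np.asarray(list(peaks), dtype=float)
    if len(x) < 2:
        raise StatsError(f"group {group!r}: need >= 2 values, got {len(x)}")
    return GroupSummary(
        group=group,
        n=len(x),
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)),
    )


def group_percent_difference(s1: GroupSummary, s2: GroupSummary) -> float:
    """Percent difference of group means, s1 as the reference."""
    if s1.mean <= 0:
        raise StatsError(f"reference group mean must be positive, got {s1.mean}")
    return 100.0 * (s2.mean - s1.mean) / s1.mean


def two_sample_t(a, b, equal_var: bool = False) -> TestResult:
    """Two-sample t-test, Welch (unequal variances) by default.

    Two-sided p-value from the t distribution with Welch–Satterthwaite
    degrees of freedom (or n1+n2-2 when ``equal_var``).
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("each sample needs >= 2 observations")
    if np.std(a) == 0 and np.std(b) == 0 and np.mean(a) == np.mean(b):
        # degenerate but well-defined: identical constants -> no evidence
        return TestResult(0.0, 1.0, float(len(a) + len(b) - 2),
                          "two-sample t (degenerate)")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    method = "Student t" if equal_var else "Welch t"
    return TestResult(float(res.statistic), float(res.pvalue),
                      float(res.df), method)


def rounds_correlation(peaks, rounds) -> TestResult:
    """Pearson correlation of ceWGT peak height with polyploidy rounds."""
    x = np.asarray(list(peaks), dtype=float)
    r_ = np.asarray(list(rounds), dtype=float)
    if len(x) != len(r_) or len(x) < 3:
        raise StatsError("need equal-length vectors with >= 3 observations")
    if np.std(x) == 0 or np.std(r_) == 0:
        raise StatsError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, r_)
    return TestResult(float(res.statistic), float(res.pvalue),
                      float(len(x) - 2), "Pearson r")


def compare_groups(models: list[PeakModel], meta: list[SpeciesMeta]) -> dict:
    """Full comparison report for a species set.

    Returns a JSON-serialisable dict with per-species peaks, group
    summaries, the percent difference of group means (P1R as reference),
    the Welch t-test and the rounds correlation.
    """
    by_species = {m.species: m for m in meta}
    peaks: dict[str, float] = {}
    rounds: dict[str, int] = {}
    for model in models:
        sp = model.species
        if sp not in by_species:
            raise StatsError(f"no metadata for species {sp!r}")
        peaks[sp] = model.peak("ceWGT")
        rounds[sp] = by_species[sp].rounds
    p1r = [peaks[s] for s in peaks if by_species[s].group == "P1R"]
    p2r = [peaks[s] for s in peaks if by_species[s].group == "P2R"]
    s1 = group_summary(p1r, "P1R")
    s2 = group_summary(p2r, "P2R")
    t = two_sample_t(p1r, p2r)
    corr = rounds_correlation(list(peaks.values()),
                              [rounds[s] for s in peaks])
    return {
        "peaks": peaks,
        "groups": {
            g.group: {"n": g.n, "mean": g.mean, "sd": g.sd, "cv": g.cv}
            for g in (s1, s2)
        },
        "percent_difference": group_percent_difference(s1, s2),
        "t_test": {"statistic": t.statistic, "p_value": t.p_value,
                   "df": t.df, "method": t.method},
        "correlation": {"statistic": corr.statistic, "p_value": corr.p_value,
                        "df": corr.df, "method": corr.method},
    }
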