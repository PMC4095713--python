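"""Case and group statistics: sampling, descriptives, histograms, tests.

Mirrors the study's two statistical stages: per case, a random sample of
exactly 100 measured cells defines row-aligned A, P and FF vectors; per
group, the five case samples are concatenated (500 cells) and summarised
with descriptive statistics, fixed-width 20-class histograms with a
matched-Gaussian overlay, one-way ANOVA between groups and two-sample
t-tests (Welch by default, since the equal-variance assumption is only
approximately met in this kind of data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DescriptiveStats",
    "Histogram",
    "TestResult",
    "CLASS_WIDTHS",
    "sample_records",
    "describe",
    "build_histogram",
    "gaussian_overlay",
    "anova_one_way",
    "t_test_two_sample",
    "significance_tier",
]

#: histogram class widths per parameter: 3.5 um^2 for A, 7 um for P, 0.05 for FF
CLASS_WIDTHS = {"area": 3.5, "perimeter": 7.0, "form_factor": 0.05}
N_CLASSES = 20


@dataclass(frozen=True)
class DescriptiveStats:
    """Sample mean, SD (n-1 denominator) and extremes."""

    n: int
    mean: float
    sd: float
    min: float
    max: float


@dataclass(frozen=True)
class Histogram:
    """Fixed-width histogram: 20 half-open classes starting at 0.

    Classes are [k*w, (k+1)*w) with the final upper edge closed; values at
    or beyond 20*w are counted in ``out_of_range``, never silently dropped.
    """

    parameter: str
    class_width: float
    edges: np.ndarray  # 21 edges
    counts: np.ndarray  # 20 counts
    n: int
    out_of_range: int

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_value: float
    df: tuple[float, ...] | float
    equal_variance: bool | None = None


def sample_records(
    db: pd.DataFrame, n: int = 100, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Draw exactly ``n`` distinct records uniformly without replacement.

    The returned frame keeps the rows aligned (each row is one cell, so the
    A, P and FF columns refer to the same cells).  Databases smaller than
    ``n`` raise with the case name rather than silently under-sampling.
    """
    if len(db) < n:
        case = db["case_id"].iloc[0] if "case_id" in db and len(db) else "<unknown>"
        raise ValueError(
            f"case {case}: database has {len(db)} records, fewer than the sample size {n}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(db), size=n, replace=False))
    return db.iloc[idx].reset_index(drop=True)


def describe(values) -> DescriptiveStats:
    """Mean, sample SD, min and max of a non-empty vector."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot describe an empty sample")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return DescriptiveStats(
        n=int(values.size),
        mean=float(values.mean()),
        sd=sd,
        min=float(values.min()),
        max=float(values.max()),
    )


def build_histogram(
    values, parameter: str, class_width: float | None = None, n_classes: int = N_CLASSES
) -> Histogram:
    """20-class fixed-width histogram starting at zero.

    Interior edges follow the half-open convention (a value exactly on an
    edge belongs to the class on its right); the top edge of the last class
    is closed.
    """
    if class_width is None:
        try:
            class_width = CLASS_WIDTHS[parameter]
        except KeyError:
            raise ValueError(
                f"no default class width for parameter {parameter!r}; pass class_width"
            ) from None
    values = np.asarray(values, dtype=float)
    edges = np.arange(n_classes + 1) * class_width
    counts, _ = np.histogram(values, bins=edges)
    in_range = values[(values >= 0) & (values <= edges[-1])]
    out_of_range = int(values.size - in_range.size)
    return Histogram(
        parameter=parameter,
        class_width=float(class_width),
        edges=edges,
        counts=counts,
        n=int(values.size),
        out_of_range=out_of_range,
    )


def gaussian_overlay(stats: DescriptiveStats, hist: Histogram) -> np.ndarray | None:
    """Gaussian curve with the sample mean/SD on the histogram's count scale.

    Returns the normal density at the class centres scaled by
    ``n * class_width`` so its integral over the classes matches the sample
    size.  A zero-SD sample has no curve (degenerate spike); ``None`` is
    returned in that case.
    """
    if stats.sd == 0:
        return None
    return stats.n * hist.class_width * sps.norm.pdf(hist.centers, loc=stats.mean, scale=stats.sd)


def anova_one_way(groups: list[np.ndarray]) -> TestResult:
    """Classical one-way ANOVA F test across two or more groups."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    n_total = sum(a.size for a in arrays)
    df = (len(arrays) - 1, n_total - len(arrays))
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:  # all observations identical: no variance anywhere
        return TestResult("anova_one_way", 0.0, 1.0, df)
    f, p = sps.f_oneway(*arrays)
    return TestResult("anova_one_way", float(f), float(p), df)


def t_test_two_sample(x, y, equal_variance: bool = False) -> TestResult:
    """Two-sided two-sample t-test; Welch (unequal variances) by default."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two values")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        # degenerate: both samples constant
        if x[0] == y[0]:
            df = x.size + y.size - 2 if equal_variance else float(x.size + y.size - 2)
            return TestResult("t_test_two_sample", 0.0, 1.0, df, equal_variance)
        raise ValueError("both samples have zero variance but different means")
    res = sps.ttest_ind(x, y, equal_var=equal_variance)
    return TestResult(
        "t_test_two_sample", float(res.statistic), float(res.pvalue), float(res.df), equal_variance
    )


def significance_tier(p: float) -> str:
    """The study's reporting tiers: significant / highly / very highly."""
    if p <= 0.001:
        return "p<=0.001"
    if p <= 0.01:
        return "p<=0.01"
    if p <= 0.05:
        return "p<=0.05"
    return "ns"
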