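"""Mean-value-scaled relative distances (RD).

For a set E = {e_1, ..., e_n} of positive values with arithmetic mean M(E),
the mean-scaling transformation is

    e_i_bar = (e_i - M(E)) / M(E),

and two relative distances follow:

    RD_E(e_i)    = |e_i_bar|           = |e_i - M(E)| / M(E)
    RD(e_i, e_j) = |e_i_bar - e_j_bar| = |e_i - e_j| / M(E).

Dividing by M(E) makes both quantities invariant to a common rescaling of
the set, so they compare morphometric sets regardless of the absolute cell
size.  Intragroup analysis applies RD_E to the five case means of one group
(similar cases have RD_E below a threshold, conventionally 10%);
intergroup analysis applies RD to the three group means of a parameter and
quantifies how much closer one stage is to another through RD ratios.

RDs are stored as fractions and rendered as percentages in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElementSet",
    "IntragroupRDReport",
    "IntergroupRDReport",
    "mean_scale",
    "rd_to_mean",
    "rd_between",
    "intragroup_report",
    "intergroup_report",
    "rd_ratio",
]

DEFAULT_THRESHOLD = 0.10


@dataclass(frozen=True)
class ElementSet:
    """A labelled set of n >= 2 positive values (typically mean values)."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("an element set needs at least two values")
        if not np.all(values > 0):
            raise ValueError("element values must be positive")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def _as_set(E) -> ElementSet:
    return E if isinstance(E, ElementSet) else ElementSet(np.asarray(E, dtype=float))


def mean_scale(E) -> np.ndarray:
    """The transformed values (e_i - M(E)) / M(E); they sum to zero."""
    E = _as_set(E)
    return (E.values - E.mean) / E.mean


def rd_to_mean(E, i: int) -> float:
    """RD_E(e_i) = |e_i - M(E)| / M(E), with 0-based index ``i``."""
    E = _as_set(E)
    if not 0 <= i < E.n:
        raise IndexError(f"index {i} out of range for a set of {E.n} elements")
    return float(abs(E.values[i] - E.mean) / E.mean)


def rd_between(E, i: int, j: int) -> float:
    """RD(e_i, e_j) = |e_i - e_j| / M(E); symmetric in (i, j)."""
    E = _as_set(E)
    for k in (i, j):
        if not 0 <= k < E.n:
            raise IndexError(f"index {k} out of range for a set of {E.n} elements")
    return float(abs(E.values[i] - E.values[j]) / E.mean)


def rd_ratio(rd_a: float, rd_b: float) -> float:
    """Ratio of two relative distances; undefined for a zero denominator."""
    if rd_b == 0:
        raise ZeroDivisionError("RD ratio undefined: the denominator RD is zero")
    return rd_a / rd_b


@dataclass(frozen=True)
class IntragroupRDReport:
    """Case-versus-group-mean relative distances for one group/parameter."""

    group: str
    parameter: str
    case_means: np.ndarray
    rd: np.ndarray  # fractions, one per case
    threshold: float
    passes: np.ndarray  # strict: RD < threshold
    max_rd: float
    max_case: int  # 1-based case number of the maximum RD

    @property
    def rd_percent(self) -> np.ndarray:
        return 100.0 * self.rd

    @property
    def n_below_threshold(self) -> int:
        return int(self.passes.sum())


def intragroup_report(
    case_means,
    parameter: str = "",
    group: str = "",
    threshold: float = DEFAULT_THRESHOLD,
) -> IntragroupRDReport:
    """RD of each case mean from the group mean, with pass flags.

    A case passes when its RD is strictly below the threshold ("variations
    less than 10%" under the default).
    """
    E = _as_set(case_means)
    rd = np.abs(mean_scale(E))
    passes = rd < threshold
    max_idx = int(np.argmax(rd))
    return IntragroupRDReport(
        group=group,
        parameter=parameter,
        case_means=E.values,
        rd=rd,
        threshold=threshold,
        passes=passes,
        max_rd=float(rd[max_idx]),
        max_case=max_idx + 1,
    )


@dataclass(frozen=True)
class IntergroupRDReport:
    """Pairwise group-mean relative distances for one parameter.

    ``rd`` maps ordered stage-pair labels to fractions; the global mean is
    the arithmetic mean of the group means (equal to the pooled mean when
    groups have equal sizes).
    """

    parameter: str
    group_labels: tuple[str, ...]
    group_means: np.ndarray
    global_mean: float
    rd: dict[tuple[str, str], float] = field(default_factory=dict)

    def rd_percent(self, pair: tuple[str, str]) -> float:
        try:
            return 100.0 * self.rd[pair]
        except KeyError:
            return 100.0 * self.rd[pair[::-1]]


def intergroup_report(
    group_means,
    parameter: str = "",
    group_labels: tuple[str, ...] = ("I", "II", "III"),
) -> IntergroupRDReport:
    """Relative distances between consecutive groups of one parameter.

    For the standard three-stage study this yields RD(I, II) and
    RD(II, III), both scaled by the global mean of the three group means.
    """
    E = _as_set(group_means)
    if E.n != len(group_labels):
        raise ValueError(f"expected {len(group_labels)} group means, got {E.n}")
    rd = {
        (group_labels[i], group_labels[i + 1]): rd_between(E, i, i + 1)
        for i in range(E.n - 1)
    }
    return IntergroupRDReport(
        parameter=parameter,
        group_labels=tuple(group_labels),
        group_means=E.values,
        global_mean=E.mean,
        rd=rd,
    )
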