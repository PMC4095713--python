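"""Bundled summary statistics of the published tooth-germ fibroblast study.

The package reproduces a published histomorphometric study of dental-pulp
fibroblasts in human tooth germs.  Fifteen tooth germs (cases), five per
developmental stage — cap (group I), early bell (group II) and late bell
(group III) — were measured on haematoxylin-eosin stained sections; for
each case a random sample of 100 cells provides the area (A, um^2),
perimeter (P, um) and form factor (FF = 4*pi*A/P^2) vectors.

The study's raw images are not deposited, but its printed per-case and
per-group summary tables and per-group perimeter-versus-area regression
fits are complete inputs for the relative-distance and regression-proximity
procedures, so they ship here as small literal tables.
"""

from __future__ import annotations

import pandas as pd

PARAMETERS = ("area", "perimeter", "form_factor")
GROUPS = ("I", "II", "III")
STAGE_OF_GROUP = {"I": "cap", "II": "early_bell", "III": "late_bell"}

# (group, case, parameter) -> (mean, sd, min, max); case 0 is the pooled
# group row (500 cells), cases 1..5 are the per-case 100-cell samples.
_CASE_ROWS: list[tuple[str, int, str, float, float, float, float]] = [
    # group I (cap stage)
    ("I", 1, "area", 18.755, 7.549, 7.129, 35.550),
    ("I", 2, "area", 14.635, 5.903, 5.078, 30.698),
    ("I", 3, "area", 16.356, 7.202, 5.317, 35.065),
    ("I", 4, "area", 20.335, 7.730, 8.556, 43.034),
    ("I", 5, "area", 18.558, 6.855, 7.530, 37.958),
    ("I", 1, "perimeter", 31.582, 11.844, 13.264, 59.180),
    ("I", 2, "perimeter", 27.712, 10.178, 10.568, 63.837),
    ("I", 3, "perimeter", 29.281, 11.222, 11.802, 59.420),
    ("I", 4, "perimeter", 31.170, 13.122, 11.082, 73.705),
    ("I", 5, "perimeter", 30.154, 11.168, 11.887, 65.114),
    ("I", 1, "form_factor", 0.272, 0.114, 0.099, 0.592),
    ("I", 2, "form_factor", 0.271, 0.111, 0.090, 0.742),
    ("I", 3, "form_factor", 0.273, 0.113, 0.109, 0.606),
    ("I", 4, "form_factor", 0.328, 0.161, 0.089, 0.891),
    ("I", 5, "form_factor", 0.303, 0.137, 0.082, 0.769),
    # group II (early bell stage)
    ("II", 1, "area", 26.058, 10.620, 8.861, 52.743),
    ("II", 2, "area", 24.212, 10.647, 7.351, 50.952),
    ("II", 3, "area", 25.629, 10.629, 9.159, 54.173),
    ("II", 4, "area", 24.499, 10.562, 7.746, 53.395),
    ("II", 5, "area", 25.538, 9.320, 9.027, 58.368),
    ("II", 1, "perimeter", 51.903, 20.556, 20.347, 117.308),
    ("II", 2, "perimeter", 51.065, 18.990, 20.127, 98.376),
    ("II", 3, "perimeter", 52.892, 19.011, 19.448, 99.785),
    ("II", 4, "perimeter", 53.228, 19.847, 22.611, 106.470),
    ("II", 5, "perimeter", 49.854, 16.851, 18.370, 97.057),
    ("II", 1, "form_factor", 0.143, 0.064, 0.032, 0.371),
    ("II", 2, "form_factor", 0.129, 0.049, 0.047, 0.285),
    ("II", 3, "form_factor", 0.129, 0.053, 0.052, 0.351),
    ("II", 4, "form_factor", 0.120, 0.042, 0.053, 0.219),
    ("II", 5, "form_factor", 0.147, 0.063, 0.054, 0.344),
    # group III (late bell stage)
    ("III", 1, "area", 32.847, 11.928, 13.594, 68.401),
    ("III", 2, "area", 31.520, 10.901, 11.755, 56.038),
    ("III", 3, "area", 30.783, 11.880, 10.719, 60.730),
    ("III", 4, "area", 34.730, 11.006, 13.937, 65.094),
    ("III", 5, "area", 34.060, 9.390, 14.367, 55.307),
    ("III", 1, "perimeter", 67.560, 23.797, 26.782, 124.882),
    ("III", 2, "perimeter", 69.061, 23.641, 30.298, 120.394),
    ("III", 3, "perimeter", 64.058, 22.609, 28.111, 125.166),
    ("III", 4, "perimeter", 69.336, 21.368, 28.125, 117.166),
    ("III", 5, "perimeter", 65.089, 19.183, 26.432, 124.000),
    ("III", 1, "form_factor", 0.105, 0.046, 0.038, 0.257),
    ("III", 2, "form_factor", 0.095, 0.039, 0.039, 0.199),
    ("III", 3, "form_factor", 0.106, 0.041, 0.042, 0.214),
    ("III", 4, "form_factor", 0.103, 0.045, 0.038, 0.289),
    ("III", 5, "form_factor", 0.114, 0.044, 0.045, 0.263),
]

_GROUP_ROWS: list[tuple[str, str, float, float, float, float]] = [
    ("I", "area", 17.733, 7.328, 5.078, 43.034),
    ("I", "perimeter", 29.980, 11.585, 10.568, 73.705),
    ("I", "form_factor", 0.289, 0.130, 0.082, 0.891),
    ("II", "area", 25.187, 10.351, 7.351, 58.368),
    ("II", "perimeter", 51.788, 19.055, 18.370, 117.308),
    ("II", "form_factor", 0.134, 0.056, 0.032, 0.371),
    ("III", "area", 32.788, 11.115, 10.719, 68.401),
    ("III", "perimeter", 67.021, 22.198, 26.432, 125.166),
    ("III", "form_factor", 0.104, 0.043, 0.038, 0.289),
]

# Published per-group ordinary least-squares fits of perimeter on area,
# P = slope * A + intercept, with the Pearson A-P correlation, n = 500.
REFERENCE_REGRESSIONS: dict[str, dict[str, float]] = {
    "I": {"slope": 1.4263, "intercept": 4.6868, "correlation": 0.9023, "n": 500},
    "II": {"slope": 1.6758, "intercept": 9.5794, "correlation": 0.9104, "n": 500},
    "III": {"slope": 1.7626, "intercept": 9.2303, "correlation": 0.8825, "n": 500},
}


def reference_case_stats() -> pd.DataFrame:
    """Per-case summary of the published study (5 cases x 3 groups x A/P/FF)."""
    return pd.DataFrame(
        _CASE_ROWS, columns=["group", "case", "parameter", "mean", "sd", "min", "max"]
    )


def reference_group_stats() -> pd.DataFrame:
    """Pooled per-group summary (500 cells per group) of the published study."""
    return pd.DataFrame(_GROUP_ROWS, columns=["group", "parameter", "mean", "sd", "min", "max"])


def case_means(group: str, parameter: str) -> list[float]:
    """The five published case means for one group and parameter, case order 1..5."""
    df = reference_case_stats()
    sel = df[(df["group"] == group) & (df["parameter"] == parameter)].sort_values("case")
    if sel.empty:
        raise KeyError(f"no published rows for group {group!r}, parameter {parameter!r}")
    return sel["mean"].tolist()


def group_means(parameter: str) -> list[float]:
    """The three published group means for one parameter, group order I, II, III."""
    df = reference_group_stats()
    sel = df[df["parameter"] == parameter].set_index("group")
    if sel.empty:
        raise KeyError(f"no published rows for parameter {parameter!r}")
    return [float(sel.loc[g, "mean"]) for g in GROUPS]
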