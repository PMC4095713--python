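"""End-to-end study orchestration.

``run_study`` drives the full analysis: synthesise (or ingest) the study
images, segment and measure every image, sample 100 records per case,
compute case/group descriptive statistics, histograms, hypothesis tests,
intra- and intergroup relative distances, per-group perimeter-area
regressions and the line-proximity ratio.  Every table is written as CSV
and the whole run is a deterministic function of the configuration and its
master seed.

``tables_report`` is the tables-only entry point: it accepts case and
group summary statistics directly (for instance the bundled published
tables) and runs just the relative-distance and regression procedures.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, datasets
from .morphometry import CASE_DB_COLUMNS, DEFAULT_ESTIMATOR, Calibration, measure_image
from .rd import IntergroupRDReport, IntragroupRDReport, intergroup_report, intragroup_report, rd_ratio
from .regression import DEFAULT_EVAL_AREA, RegressionFit, evaluate_line, fit_linear, line_proximity_ratio
from .segmentation import (
    DEFAULT_THRESHOLD,
    ThresholdSpec,
    enhance_contrast,
    label_regions,
    remove_scrap,
    threshold_rgb,
)
from .stats import (
    CLASS_WIDTHS,
    anova_one_way,
    build_histogram,
    describe,
    gaussian_overlay,
    sample_records,
    significance_tier,
    t_test_two_sample,
)
from .synthetic import DEFAULT_CALIBRATION_UM_PER_PX, StageParams, stage_defaults, synthesize_case_images

__all__ = [
    "StudyConfig",
    "StudyReport",
    "run_study",
    "tables_report",
    "read_case_database",
    "write_case_database",
    "PARAMETER_COLUMNS",
]

logger = logging.getLogger(__name__)

PARAMETER_COLUMNS = {"area": "area_um2", "perimeter": "perimeter_um", "form_factor": "form_factor"}

#: the study's per-case record count range; counts outside it are logged
EXPECTED_RECORDS_PER_CASE = (500, 700)


@dataclass
class StudyConfig:
    """Declarative configuration of one study run."""

    mode: str = "synthetic"  # "synthetic" | "images"
    seed: int = 0
    n_cases: int = 5
    images_per_case: int = 5
    cells_per_image: int = 110
    image_shape: tuple[int, int] = (2048, 2048)  # 256 um field at the default calibration
    calibration_um_per_px: float = DEFAULT_CALIBRATION_UM_PER_PX
    magnification: str = "x200"
    threshold: ThresholdSpec = field(default_factory=lambda: DEFAULT_THRESHOLD)
    apply_contrast_stretch: bool = False
    contrast_percentiles: tuple[float, float] = (1.0, 99.0)
    min_area_um2: float = 5.0
    perimeter_estimator: str = DEFAULT_ESTIMATOR
    sample_size: int = 100
    rd_threshold: float = 0.10
    regression_eval_area: float = DEFAULT_EVAL_AREA
    save_images: bool = False
    make_plots: bool = False
    images_root: str | None = None  # images mode: root of <group>/<case>/<image> tree
    stage_params: dict[str, StageParams] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "images"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in ("n_cases", "images_per_case", "sample_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("calibration_um_per_px", "min_area_um2", "rd_threshold"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.mode == "images" and not self.images_root:
            raise ValueError("images mode requires images_root")

    @property
    def min_area_px(self) -> int:
        """Scrap cut-off in pixels at the configured calibration."""
        return max(1, round(self.min_area_um2 / self.calibration_um_per_px**2))

    @property
    def calibration(self) -> Calibration:
        return Calibration(self.calibration_um_per_px, self.magnification)

    def stages(self) -> dict[str, StageParams]:
        return self.stage_params or stage_defaults(cells_per_image=self.cells_per_image)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["threshold"] = {"r": list(self.threshold.r), "g": list(self.threshold.g), "b": list(self.threshold.b)}
        if self.stage_params is not None:
            d["stage_params"] = {k: asdict(v) for k, v in self.stage_params.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "threshold" in d and not isinstance(d["threshold"], ThresholdSpec):
            t = d["threshold"]
            d["threshold"] = ThresholdSpec(tuple(t["r"]), tuple(t["g"]), tuple(t["b"]))
        if d.get("stage_params"):
            d["stage_params"] = {
                k: v if isinstance(v, StageParams) else StageParams(**v)
                for k, v in d["stage_params"].items()
            }
        for key in ("image_shape", "contrast_percentiles"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class StudyReport:
    """All tables produced by one study run."""

    case_stats: pd.DataFrame
    group_stats: pd.DataFrame
    anova: pd.DataFrame
    t_tests: pd.DataFrame
    intragroup: pd.DataFrame
    intergroup: pd.DataFrame
    rd_ratios: dict[str, float]
    regressions: dict[str, RegressionFit]
    proximity_ratio: float
    histograms: pd.DataFrame
    provenance: dict
    intragroup_reports: list[IntragroupRDReport] = field(default_factory=list)
    intergroup_reports: list[IntergroupRDReport] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("case_stats", "group_stats", "anova", "t_tests", "intragroup", "intergroup", "histograms"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        reg = pd.DataFrame(
            [
                {"group": g, "slope": f.slope, "intercept": f.intercept, "correlation": f.correlation, "n": f.n}
                for g, f in self.regressions.items()
            ]
        )
        reg.to_csv(out / "regressions.csv", index=False)
        summary = {
            "rd_ratios": self.rd_ratios,
            "proximity_ratio": self.proximity_ratio,
            "provenance": self.provenance,
        }
        (out / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        return out


# ---------------------------------------------------------------------------
# Case databases (the interchange CSV format)
# ---------------------------------------------------------------------------

def write_case_database(db: pd.DataFrame, path: str | Path) -> None:
    """Write a case database CSV with the canonical column order."""
    missing = [c for c in CASE_DB_COLUMNS if c not in db.columns]
    if missing:
        raise ValueError(f"case database missing columns: {missing}")
    db[CASE_DB_COLUMNS].to_csv(path, index=False)


def read_case_database(path: str | Path) -> pd.DataFrame:
    """Read and validate a case database CSV.

    Schema errors name the missing column; malformed numeric fields are
    reported with their (1-based, header-inclusive) line numbers.
    """
    db = pd.read_csv(path)
    if db.empty:
        raise ValueError(f"{path}: empty case database")
    missing = [c for c in CASE_DB_COLUMNS if c not in db.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in ("area_um2", "perimeter_um", "form_factor"):
        numeric = pd.to_numeric(db[col], errors="coerce")
        bad = db.index[numeric.isna()]
        if len(bad):
            lines = ", ".join(str(i + 2) for i in bad[:5])
            raise ValueError(f"{path}: non-numeric {col} at line(s) {lines}")
        db[col] = numeric
    return db[CASE_DB_COLUMNS]


# ---------------------------------------------------------------------------
# Image segmentation + measurement for one image
# ---------------------------------------------------------------------------

def segment_and_measure(
    image: np.ndarray, config: StudyConfig, case_id: str, image_id: str
) -> pd.DataFrame:
    """Run the measurement front end on one RGB image."""
    if config.apply_contrast_stretch:
        image = enhance_contrast(image, config.contrast_percentiles)
    mask = threshold_rgb(image, config.threshold)
    mask = remove_scrap(mask, config.min_area_px)
    labeled = label_regions(mask, connectivity=8)
    return measure_image(labeled, config.calibration, case_id, image_id, config.perimeter_estimator)


def _iter_case_images(config: StudyConfig, out_dir: Path | None):
    """Yield (group_label, stage, case_id, [(image_id, image), ...]) per case."""
    if config.mode == "synthetic":
        stages = config.stages()
        root = np.random.SeedSequence(config.seed)
        group_seqs = root.spawn(len(stages))
        for (stage, params), gseq, glabel in zip(stages.items(), group_seqs, datasets.GROUPS):
            for case_idx, cseq in enumerate(gseq.spawn(config.n_cases), start=1):
                case_id = f"{stage}_case{case_idx}"
                images = []
                for image_id, image, _truth, _records in synthesize_case_images(
                    params,
                    case_id,
                    config.images_per_case,
                    config.image_shape,
                    config.calibration_um_per_px,
                    cseq,
                ):
                    if config.save_images and out_dir is not None:
                        import imageio.v3 as iio

                        img_dir = out_dir / "images" / stage / f"case{case_idx}"
                        img_dir.mkdir(parents=True, exist_ok=True)
                        iio.imwrite(img_dir / f"{image_id}.png", image)
                    images.append((image_id, image))
                yield glabel, stage, case_id, images
    else:
        import imageio.v3 as iio

        root = Path(config.images_root)
        if not root.is_dir():
            raise FileNotFoundError(f"images_root {root} does not exist")
        group_dirs = sorted(p for p in root.iterdir() if p.is_dir())
        for glabel, gdir in zip(datasets.GROUPS, group_dirs):
            for cdir in sorted(p for p in gdir.iterdir() if p.is_dir()):
                case_id = f"{gdir.name}_{cdir.name}"
                images = [
                    (path.stem, iio.imread(path))
                    for path in sorted(cdir.glob("*.png")) + sorted(cdir.glob("*.tif*"))
                ]
                yield glabel, gdir.name, case_id, images


# ---------------------------------------------------------------------------
# The full study
# ---------------------------------------------------------------------------

def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> StudyReport:
    """Execute the complete pipeline and return (and optionally write) the report."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        (out / "databases").mkdir(parents=True, exist_ok=True)

    sampling_root = np.random.SeedSequence((config.seed, 1))

    case_rows = []
    case_samples: dict[tuple[str, str], pd.DataFrame] = {}  # (group, case_id) -> sample
    group_of_case: dict[str, str] = {}
    for (glabel, stage, case_id, images), samp_seq in zip(
        _iter_case_images(config, out), _seed_stream(sampling_root)
    ):
        frames = []
        for image_id, image in images:
            df = segment_and_measure(image, config, case_id, image_id)
            logger.info("%s/%s: %d regions", case_id, image_id, len(df))
            frames.append(df)
        db = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=CASE_DB_COLUMNS)
        if config.mode == "synthetic" and config.images_per_case == 5:
            lo, hi = EXPECTED_RECORDS_PER_CASE
            if not lo <= len(db) <= hi:
                logger.warning(
                    "%s: %d records, outside the study's usual %d-%d per case",
                    case_id, len(db), lo, hi,
                )
        if out is not None:
            write_case_database(db, out / "databases" / f"{case_id}.csv")
        sample = sample_records(db, config.sample_size, np.random.default_rng(samp_seq))
        case_samples[(glabel, case_id)] = sample
        group_of_case[case_id] = glabel
        for param, col in PARAMETER_COLUMNS.items():
            st = describe(sample[col])
            case_rows.append(
                (glabel, case_id, param, st.n, st.mean, st.sd, st.min, st.max, len(db))
            )
    case_stats = pd.DataFrame(
        case_rows,
        columns=["group", "case_id", "parameter", "n", "mean", "sd", "min", "max", "db_records"],
    )

    # group vectors: concatenation of the per-case samples
    group_vectors: dict[tuple[str, str], np.ndarray] = {}
    group_rows = []
    hist_rows = []
    for glabel in case_stats["group"].unique():
        cases = [s for (g, _), s in case_samples.items() if g == glabel]
        pooled = pd.concat(cases, ignore_index=True)
        for param, col in PARAMETER_COLUMNS.items():
            vec = pooled[col].to_numpy()
            group_vectors[(glabel, param)] = vec
            st = describe(vec)
            group_rows.append((glabel, param, st.n, st.mean, st.sd, st.min, st.max))
            hist = build_histogram(vec, param, CLASS_WIDTHS[param])
            overlay = gaussian_overlay(st, hist)
            for k in range(hist.counts.size):
                hist_rows.append(
                    (glabel, param, hist.edges[k], hist.edges[k + 1], int(hist.counts[k]),
                     float(overlay[k]) if overlay is not None else np.nan, hist.out_of_range)
                )
    group_stats = pd.DataFrame(
        group_rows, columns=["group", "parameter", "n", "mean", "sd", "min", "max"]
    )
    histograms = pd.DataFrame(
        hist_rows,
        columns=["group", "parameter", "edge_low", "edge_high", "count", "gaussian_overlay", "out_of_range"],
    )

    groups = list(dict.fromkeys(group_stats["group"]))

    # intergroup hypothesis tests on the pooled vectors
    anova_rows = []
    for param in PARAMETER_COLUMNS:
        res = anova_one_way([group_vectors[(g, param)] for g in groups])
        anova_rows.append((param, res.statistic, res.p_value, res.df[0], res.df[1], significance_tier(res.p_value)))
    anova = pd.DataFrame(anova_rows, columns=["parameter", "F", "p_value", "df_between", "df_within", "tier"])

    # pairwise t-tests: intergroup on pooled vectors and intragroup between cases
    t_rows = []
    for param, col in PARAMETER_COLUMNS.items():
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                res = t_test_two_sample(group_vectors[(groups[i], param)], group_vectors[(groups[j], param)])
                t_rows.append(("intergroup", f"{groups[i]} vs {groups[j]}", param,
                               res.statistic, res.p_value, significance_tier(res.p_value)))
    for glabel in groups:
        cases = [(cid, s) for (g, cid), s in case_samples.items() if g == glabel]
        for i in range(len(cases)):
            for j in range(i + 1, len(cases)):
                for param, col in PARAMETER_COLUMNS.items():
                    res = t_test_two_sample(cases[i][1][col], cases[j][1][col])
                    t_rows.append((f"intragroup {glabel}", f"case {i + 1} vs case {j + 1}", param,
                                   res.statistic, res.p_value, significance_tier(res.p_value)))
    t_tests = pd.DataFrame(t_rows, columns=["level", "pair", "parameter", "t", "p_value", "tier"])

    # relative distances
    intra_rows, intra_reports = [], []
    for glabel in groups:
        for param in PARAMETER_COLUMNS:
            sel = case_stats[(case_stats["group"] == glabel) & (case_stats["parameter"] == param)]
            if len(sel) < 2:  # intragroup RD needs at least two case means
                continue
            rep = intragroup_report(sel["mean"].to_numpy(), param, glabel, config.rd_threshold)
            intra_reports.append(rep)
            for k, cid in enumerate(sel["case_id"]):
                intra_rows.append((glabel, param, cid, rep.case_means[k],
                                   rep.rd_percent[k], bool(rep.passes[k])))
    intragroup = pd.DataFrame(
        intra_rows, columns=["group", "parameter", "case_id", "case_mean", "rd_percent", "below_threshold"]
    )

    inter_rows, inter_reports, rd_ratios = [], [], {}
    gs = group_stats.set_index(["group", "parameter"])["mean"]
    for param in PARAMETER_COLUMNS:
        means = [float(gs[g, param]) for g in groups]
        rep = intergroup_report(means, param, tuple(groups))
        inter_reports.append(rep)
        for pair, val in rep.rd.items():
            inter_rows.append((param, f"{pair[0]} vs {pair[1]}", 100.0 * val, rep.global_mean))
        pairs = list(rep.rd.values())
        if len(pairs) == 2 and pairs[1] > 0:
            rd_ratios[param] = rd_ratio(pairs[0], pairs[1])
    intergroup = pd.DataFrame(inter_rows, columns=["parameter", "pair", "rd_percent", "global_mean"])

    # per-group regression of perimeter on area and the proximity procedure
    regressions = {
        g: fit_linear(group_vectors[(g, "area")], group_vectors[(g, "perimeter")]) for g in groups
    }
    if len(groups) == 3:
        proximity = line_proximity_ratio(*(regressions[g] for g in groups), area=config.regression_eval_area)
    else:
        proximity = float("nan")

    cfg = config.to_dict()
    provenance = {
        "seed": config.seed,
        "pulpmorph_version": __version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
    }

    report = StudyReport(
        case_stats=case_stats,
        group_stats=group_stats,
        anova=anova,
        t_tests=t_tests,
        intragroup=intragroup,
        intergroup=intergroup,
        rd_ratios=rd_ratios,
        regressions=regressions,
        proximity_ratio=proximity,
        histograms=histograms,
        provenance=provenance,
        intragroup_reports=intra_reports,
        intergroup_reports=inter_reports,
    )
    if out is not None:
        report.write(out)
        if config.make_plots:
            from . import plots

            plots.write_report_plots(report, out / "plots")
    return report


def _seed_stream(root: np.random.SeedSequence):
    while True:
        yield root.spawn(1)[0]


# ---------------------------------------------------------------------------
# Tables-only mode
# ---------------------------------------------------------------------------

def tables_report(
    case_stats: pd.DataFrame | None = None,
    group_stats: pd.DataFrame | None = None,
    regressions: dict[str, RegressionFit] | None = None,
    rd_threshold: float = 0.10,
    eval_area: float = DEFAULT_EVAL_AREA,
) -> dict:
    """Relative-distance and regression procedures from summary tables alone.

    Defaults to the bundled published study summary, so the printed tables
    drive the RD framework and the line-proximity procedure without any
    image.  Returns a dict with intragroup/intergroup frames, RD ratios,
    line values at ``eval_area`` and the proximity ratio.
    """
    if case_stats is None:
        case_stats = datasets.reference_case_stats().rename(columns={"case": "case_id"})
        case_stats["group"] = case_stats["group"].astype(str)
    if group_stats is None:
        group_stats = datasets.reference_group_stats()
    if regressions is None:
        regressions = {
            g: RegressionFit(**datasets.REFERENCE_REGRESSIONS[g]) for g in datasets.GROUPS
        }

    groups = list(dict.fromkeys(group_stats["group"]))
    intra_rows = []
    for glabel in groups:
        for param in PARAMETER_COLUMNS:
            sel = case_stats[(case_stats["group"] == glabel) & (case_stats["parameter"] == param)]
            if sel.empty:
                continue
            rep = intragroup_report(sel["mean"].to_numpy(), param, str(glabel), rd_threshold)
            intra_rows.append(
                {
                    "group": glabel,
                    "parameter": param,
                    "rd_percent": list(np.round(rep.rd_percent, 4)),
                    "n_below_threshold": rep.n_below_threshold,
                    "max_rd_percent": 100.0 * rep.max_rd,
                    "max_case": rep.max_case,
                }
            )

    gs = group_stats.set_index(["group", "parameter"])["mean"]
    inter_rows, ratios = [], {}
    for param in PARAMETER_COLUMNS:
        means = [float(gs[g, param]) for g in groups]
        rep = intergroup_report(means, param, tuple(str(g) for g in groups))
        for pair, val in rep.rd.items():
            inter_rows.append(
                {"parameter": param, "pair": f"{pair[0]} vs {pair[1]}",
                 "rd_percent": 100.0 * val, "global_mean": rep.global_mean}
            )
        vals = list(rep.rd.values())
        if len(vals) == 2 and vals[1] > 0:
            ratios[param] = rd_ratio(vals[0], vals[1])

    line_values = {g: evaluate_line(f, eval_area) for g, f in regressions.items()}
    proximity = (
        line_proximity_ratio(*(regressions[g] for g in groups), area=eval_area)
        if len(groups) == 3
        else float("nan")
    )
    return {
        "intragroup": pd.DataFrame(intra_rows),
        "intergroup": pd.DataFrame(inter_rows),
        "rd_ratios": ratios,
        "line_values": line_values,
        "proximity_ratio": proximity,
        "eval_area": eval_area,
    }
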