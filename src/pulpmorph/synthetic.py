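"""Synthetic study generator: cell populations, rendered images, ground truth.

The original study measured fibroblasts on HE-stained sections that are not
deposited, so this module synthesises a complete study with the same design
(3 stage groups x 5 cases x 5 images) and the same statistical structure:

* per-cell area A is drawn from a normal truncated at zero with the
  published group mean/SD;
* per-cell form factor FF is drawn from a normal truncated to the band
  observed in the published tables (mean - 1.65 SD .. mean + 4.5 SD,
  intersected with (0, 1]);
* A and FF are negatively coupled through a Gaussian copula (default
  rank correlation -0.85): within a group, larger cells are more elongated.
  This reproduces the published quasilinear perimeter-area dependence
  (Pearson r about 0.9) that independent draws cannot produce;
* the perimeter follows from the form-factor definition,
  P = sqrt(4*pi*A / FF).

Cells are rendered as star-like (cap stage) or fusiform (bell stages)
polygons whose analytic area/perimeter are recorded as ground truth, placed
without overlap, painted over a uniform background and corrupted with
additive Gaussian pixel noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm
from skimage.draw import polygon as draw_polygon
from skimage.measure import label as sk_label

from . import datasets
from .geometry import (
    ShapeSpec,
    aspect_ratio_for_ff,
    generate_contour,
    polygon_area_perimeter,
    star_amplitude_for_ff,
)

__all__ = [
    "StageParams",
    "GroundTruthRecord",
    "PlacementError",
    "stage_defaults",
    "sample_area_ff",
    "generate_stage_records",
    "rasterize_polygon",
    "place_cells",
    "render_study_image",
    "synthesize_case_images",
    "generate_study",
    "ground_truth_frame",
]

logger = logging.getLogger(__name__)

#: microns per pixel used by the default synthetic study. Chosen so the most
#: elongated late-bell cells (FF ~ 0.1) stay several pixels wide: at 0.25
#: um/px their rasters thin to 1-px chains or fragments (form factors above
#: 1 and strongly shape-dependent perimeter bias), while at 0.125 um/px all
#: perimeter estimators agree with the polygon oracle to within ~5% on every
#: stage.
DEFAULT_CALIBRATION_UM_PER_PX = 0.125

_MIN_SEMI_MINOR_PX = 1.5  # fusiform cells never thinner than this
_MIN_INNER_RADIUS_PX = 1.2  # star cores never thinner than this


@dataclass
class StageParams:
    """Population and rendering parameters of one developmental stage.

    Means and SDs are the published group-level values (area in um^2, FF
    dimensionless).  ``ff_area_coupling`` is the Gaussian-copula correlation
    between A and FF; ``ff_sd_below``/``ff_sd_above`` bound the FF truncation
    band in SD units around the mean (the published group minima sit 1.5-1.8
    SD below the means, the maxima 4.2-4.6 SD above).
    """

    stage: str
    mean_area: float
    sd_area: float
    mean_ff: float
    sd_ff: float
    ff_area_coupling: float = -0.85
    ff_sd_below: float = 1.65
    ff_sd_above: float = 4.5
    cells_per_image: int = 110
    shape_family: str = "star"
    lobe_count: int = 5
    vertex_count: int = 128
    foreground_rgb: tuple[int, int, int] = (120, 60, 140)
    background_rgb: tuple[int, int, int] = (225, 190, 210)
    noise_sd: float = 8.0
    min_area: float = 1.0  # um^2, rendering floor so every cell rasterises

    def __post_init__(self) -> None:
        if not self.mean_area > 0:
            raise ValueError("mean_area must be positive")
        if not 0 < self.mean_ff <= 1:
            raise ValueError("mean_ff must lie in (0, 1]")
        if self.sd_area < 0 or self.sd_ff < 0:
            raise ValueError("standard deviations must be non-negative")
        if not -1.0 < self.ff_area_coupling < 1.0:
            raise ValueError("ff_area_coupling must lie in (-1, 1)")
        if self.shape_family not in ("star", "fusiform"):
            raise ValueError(f"unknown shape family {self.shape_family!r}")
        if self.cells_per_image < 0:
            raise ValueError("cells_per_image must be non-negative")

    @property
    def ff_bounds(self) -> tuple[float, float]:
        lo = max(1e-9, self.mean_ff - self.ff_sd_below * self.sd_ff)
        hi = min(1.0, self.mean_ff + self.ff_sd_above * self.sd_ff)
        return lo, hi


def stage_defaults(**overrides) -> dict[str, StageParams]:
    """Default parameters of the three stages, from the published group rows.

    Cap-stage cells are star-like, bell-stage cells fusiform.  Keyword
    overrides are applied to every stage (e.g. ``cells_per_image=30`` for a
    scaled-down study).
    """
    stats = datasets.reference_group_stats().set_index(["group", "parameter"])["mean"]
    sds = datasets.reference_group_stats().set_index(["group", "parameter"])["sd"]
    out: dict[str, StageParams] = {}
    for group, stage in datasets.STAGE_OF_GROUP.items():
        out[stage] = StageParams(
            stage=stage,
            mean_area=float(stats[group, "area"]),
            sd_area=float(sds[group, "area"]),
            mean_ff=float(stats[group, "form_factor"]),
            sd_ff=float(sds[group, "form_factor"]),
            shape_family="star" if stage == "cap" else "fusiform",
            **overrides,
        )
    return out


@dataclass
class GroundTruthRecord:
    """Analytic truth for one placed cell: the polygon and its measures."""

    case_id: str
    image_id: str
    cell_id: int
    polygon: np.ndarray  # (n, 2) vertices in microns
    area_true: float
    perimeter_true: float
    ff_true: float


class PlacementError(RuntimeError):
    """Raised when a cell cannot be placed without overlap."""


# ---------------------------------------------------------------------------
# Statistical sampling
# ---------------------------------------------------------------------------

def sample_area_ff(params: StageParams, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` coupled (area, form factor) pairs for one stage.

    Marginals: A ~ Normal(mean_area, sd_area) truncated at zero; FF ~
    Normal(mean_ff, sd_ff) truncated to ``params.ff_bounds``.  The Gaussian
    copula with correlation ``ff_area_coupling`` couples the two.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rho = params.ff_area_coupling
    z_a = rng.standard_normal(n)
    z_f = rho * z_a + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    u_a, u_f = norm.cdf(z_a), norm.cdf(z_f)

    if params.sd_area == 0:
        area = np.full(n, params.mean_area)
    else:
        a = (0.0 - params.mean_area) / params.sd_area
        area = truncnorm.ppf(u_a, a, np.inf, loc=params.mean_area, scale=params.sd_area)

    if params.sd_ff == 0:
        ff = np.full(n, params.mean_ff)
    else:
        lo, hi = params.ff_bounds
        a, b = (lo - params.mean_ff) / params.sd_ff, (hi - params.mean_ff) / params.sd_ff
        ff = truncnorm.ppf(u_f, a, b, loc=params.mean_ff, scale=params.sd_ff)
    return area, ff


def generate_stage_records(params: StageParams, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw ``n`` cell records (area, perimeter, form_factor) statistically.

    Bypasses imaging: the perimeter is derived from the form-factor
    definition, P = sqrt(4*pi*A/FF).  Useful for fast statistical tests.
    """
    area, ff = sample_area_ff(params, n, rng)
    perimeter = np.sqrt(4.0 * np.pi * area / ff)
    return pd.DataFrame({"area": area, "perimeter": perimeter, "form_factor": ff})


# ---------------------------------------------------------------------------
# Shape construction and rasterisation
# ---------------------------------------------------------------------------

def _shape_for_targets(
    params: StageParams, area: float, ff: float, rotation: float, calibration: float
) -> ShapeSpec:
    """Shape spec approximately realising target area (um^2) and form factor."""
    area = max(area, params.min_area)
    base_radius = float(np.sqrt(area / np.pi))
    if params.shape_family == "star":
        amp = star_amplitude_for_ff(ff, params.lobe_count, params.vertex_count)
        # keep the star core at least ~1 px wide so the raster stays connected
        max_amp = max(0.0, 1.0 - _MIN_INNER_RADIUS_PX * calibration / base_radius)
        return ShapeSpec(
            "star",
            base_radius,
            lobe_amplitude=min(amp, max_amp),
            lobe_count=params.lobe_count,
            rotation=rotation,
            vertex_count=params.vertex_count,
        )
    aspect = aspect_ratio_for_ff(ff, params.vertex_count)
    # semi-minor axis b = base_radius / sqrt(aspect); keep b above the raster floor
    max_aspect = max(1.0, (base_radius / (_MIN_SEMI_MINOR_PX * calibration)) ** 2)
    return ShapeSpec(
        "fusiform",
        base_radius,
        aspect_ratio=min(aspect, max_aspect),
        rotation=rotation,
        vertex_count=params.vertex_count,
    )


def rasterize_polygon(
    polygon: np.ndarray, calibration: float, image_shape: tuple[int, int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel (rows, cols) covered by a polygon given in microns.

    Pixel centres sit at integer coordinates; ``polygon / calibration`` maps
    microns to pixel coordinates with x -> column and y -> row.
    """
    pts = np.asarray(polygon, dtype=float) / calibration
    rows, cols = pts[:, 1], pts[:, 0]
    # rasterise in a non-negative frame (negative indices would be dropped)
    # using an integer offset, so the pixel set translates with the polygon
    r_off = int(np.floor(rows.min())) - 2
    c_off = int(np.floor(cols.min())) - 2
    rr, cc = draw_polygon(rows - r_off, cols - c_off)
    rr, cc = rr + r_off, cc + c_off
    if image_shape is not None:
        keep = (rr >= 0) & (rr < image_shape[0]) & (cc >= 0) & (cc < image_shape[1])
        rr, cc = rr[keep], cc[keep]
    return rr, cc


def place_cells(
    params: StageParams,
    image_shape: tuple[int, int],
    calibration: float,
    rng: np.random.Generator,
    case_id: str = "case",
    image_id: str = "image",
    n_cells: int | None = None,
    max_retries: int = 400,
) -> list[GroundTruthRecord]:
    """Place ``n_cells`` non-overlapping cells inside an image frame.

    Each cell's target (A, FF) pair is drawn from the stage distribution,
    realised as a polygon, and dropped at random positions until its
    footprint (with a 2 px clearance so neighbouring cells never touch,
    even diagonally) is free.  Cells are placed largest-first so the big
    elongated ones are not left for a crowded frame; this reorders the
    cell ids but not the joint (A, FF) distribution.  Exhausting
    ``max_retries`` positions raises :class:`PlacementError` with the
    offending cell's context.
    """
    n = params.cells_per_image if n_cells is None else n_cells
    h, w = image_shape
    occupied = np.zeros(image_shape, dtype=bool)
    records: list[GroundTruthRecord] = []
    areas, ffs = sample_area_ff(params, n, rng) if n else (np.array([]), np.array([]))
    order = np.argsort(-areas) if n else np.array([], dtype=int)
    areas, ffs = areas[order], ffs[order]

    for cell_idx in range(n):
        spec = _shape_for_targets(
            params, float(areas[cell_idx]), float(ffs[cell_idx]),
            rotation=float(rng.uniform(0.0, 2.0 * np.pi)), calibration=calibration,
        )
        poly = generate_contour(spec)
        rr0, cc0 = rasterize_polygon(poly, calibration)
        if rr0.size == 0 or not _is_connected(rr0, cc0):
            # raster floor guards make this rare; fall back to a plain disc
            spec = replace(spec, lobe_amplitude=0.0, aspect_ratio=1.0)
            poly = generate_contour(spec)
            rr0, cc0 = rasterize_polygon(poly, calibration)
        # footprint dilated by a 2 px clearance so neighbouring cells never
        # touch, even diagonally
        rrd, ccd = _dilate_footprint(rr0, cc0, margin=2)
        r_lo, r_hi = rrd.min(), rrd.max()
        c_lo, c_hi = ccd.min(), ccd.max()
        if r_hi - r_lo >= h or c_hi - c_lo >= w:
            raise PlacementError(
                f"{case_id}/{image_id}: cell {cell_idx} ({params.shape_family}, "
                f"A={areas[cell_idx]:.1f} um^2) exceeds the image frame"
            )
        placed = False
        for _ in range(max_retries):
            dr = int(rng.integers(-r_lo, h - 1 - r_hi, endpoint=True))
            dc = int(rng.integers(-c_lo, w - 1 - c_hi, endpoint=True))
            if not occupied[rrd + dr, ccd + dc].any():
                rr, cc = rr0 + dr, cc0 + dc
                occupied[rr, cc] = True
                shift = np.array([dc * calibration, dr * calibration])
                poly_placed = poly + shift
                area_t, perim_t = polygon_area_perimeter(poly_placed)
                records.append(
                    GroundTruthRecord(
                        case_id=case_id,
                        image_id=image_id,
                        cell_id=cell_idx + 1,
                        polygon=poly_placed,
                        area_true=area_t,
                        perimeter_true=perim_t,
                        ff_true=4.0 * np.pi * area_t / perim_t**2,
                    )
                )
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"{case_id}/{image_id}: could not place cell {cell_idx} after "
                f"{max_retries} attempts; reduce cells_per_image or enlarge the image"
            )
    return records


def _is_connected(rr: np.ndarray, cc: np.ndarray) -> bool:
    r0, c0 = rr.min(), cc.min()
    m = np.zeros((rr.max() - r0 + 1, cc.max() - c0 + 1), dtype=bool)
    m[rr - r0, cc - c0] = True
    return int(sk_label(m, connectivity=2).max()) == 1


def _dilate_footprint(rr: np.ndarray, cc: np.ndarray, margin: int) -> tuple[np.ndarray, np.ndarray]:
    """Pixel set expanded by a square structuring element of radius ``margin``."""
    from scipy.ndimage import binary_dilation

    r0, c0 = rr.min() - margin, cc.min() - margin
    m = np.zeros((rr.max() - r0 + margin + 1, cc.max() - c0 + margin + 1), dtype=bool)
    m[rr - r0, cc - c0] = True
    m = binary_dilation(m, structure=np.ones((2 * margin + 1, 2 * margin + 1), dtype=bool))
    rd, cd = np.nonzero(m)
    return rd + r0, cd + c0


def render_study_image(
    records: list[GroundTruthRecord],
    params: StageParams,
    image_shape: tuple[int, int],
    calibration: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Paint placed cells into an RGB image; return (image, truth labels).

    The truth label array holds 0 for background and the 1-based record
    index for each painted cell pixel; it is the segmentation ground truth.
    Overlapping records violate the placement contract and raise
    :class:`PlacementError`.
    """
    truth = np.zeros(image_shape, dtype=np.int32)
    for idx, rec in enumerate(records, start=1):
        rr, cc = rasterize_polygon(rec.polygon, calibration, image_shape)
        if truth[rr, cc].any():
            raise PlacementError(
                f"{rec.case_id}/{rec.image_id}: cell {rec.cell_id} overlaps a previous cell"
            )
        truth[rr, cc] = idx
    img = np.empty((*image_shape, 3), dtype=float)
    img[:] = params.background_rgb
    img[truth > 0] = params.foreground_rgb
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), truth


# ---------------------------------------------------------------------------
# Whole-study generation
# ---------------------------------------------------------------------------

def synthesize_case_images(
    params: StageParams,
    case_id: str,
    images_per_case: int,
    image_shape: tuple[int, int],
    calibration: float,
    seed_seq: np.random.SeedSequence,
):
    """Yield (image_id, rgb image, truth labels, records) for one case."""
    for img_idx, child in enumerate(seed_seq.spawn(images_per_case), start=1):
        rng = np.random.default_rng(child)
        image_id = f"img{img_idx:02d}"
        records = place_cells(params, image_shape, calibration, rng, case_id, image_id)
        image, truth = render_study_image(records, params, image_shape, calibration, rng)
        yield image_id, image, truth, records


def ground_truth_frame(records: list[GroundTruthRecord]) -> pd.DataFrame:
    """Tabulate ground-truth records; polygons serialised as WKT."""
    from shapely.geometry import Polygon

    return pd.DataFrame(
        {
            "case_id": [r.case_id for r in records],
            "image_id": [r.image_id for r in records],
            "cell_id": [r.cell_id for r in records],
            "area_true": [r.area_true for r in records],
            "perimeter_true": [r.perimeter_true for r in records],
            "ff_true": [r.ff_true for r in records],
            "polygon_wkt": [Polygon(r.polygon).wkt for r in records],
        }
    )


def generate_study(
    out_dir: str | Path,
    stage_params: dict[str, StageParams] | None = None,
    n_cases: int = 5,
    images_per_case: int = 5,
    image_shape: tuple[int, int] = (2048, 2048),
    calibration: float = DEFAULT_CALIBRATION_UM_PER_PX,
    seed: int = 0,
) -> Path:
    """Write a complete synthetic study to disk; return the study root.

    Layout: ``<out>/<stage>/<case>/<image>.png`` plus a single
    ``ground_truth.csv``.  The whole tree is a deterministic function of
    ``seed`` (byte-identical CSV on repeated runs).
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    stage_params = stage_params or stage_defaults()
    root_seq = np.random.SeedSequence(seed)
    all_records: list[GroundTruthRecord] = []
    for params, group_seq in zip(stage_params.values(), root_seq.spawn(len(stage_params))):
        for case_idx, case_seq in enumerate(group_seq.spawn(n_cases), start=1):
            case_id = f"{params.stage}_case{case_idx}"
            case_dir = out / params.stage / f"case{case_idx}"
            case_dir.mkdir(parents=True, exist_ok=True)
            for image_id, image, _truth, records in synthesize_case_images(
                params, case_id, images_per_case, image_shape, calibration, case_seq
            ):
                try:
                    iio.imwrite(case_dir / f"{image_id}.png", image)
                except OSError as exc:  # pragma: no cover - I/O failure path
                    raise OSError(f"failed writing {case_dir / image_id}.png: {exc}") from exc
                all_records.extend(records)
            logger.info("generated %s (%d images)", case_id, images_per_case)
    ground_truth_frame(all_records).to_csv(out / "ground_truth.csv", index=False)
    return out
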