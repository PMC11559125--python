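"""Synthetic SpaceRanger-style capture areas with planted ground truth.

Every other module is testable without downloading anything: this module
writes complete capture-area bundles (positions, scale factors, counts,
hires PNG with landmark blobs) sampled from one synthetic tissue field, and
a group layout that mirrors a three-area stitching design — two areas
partially overlapping and a third adjacent across a gap.

The tissue field is a two-region step in global x: a "white-matter-like"
region and a "cortex-like" region, each with its own Poisson mean vector
over a small marker/housekeeping gene panel.  Spots of different areas that
occupy the same nominal global lattice position draw their counts from the
same regional mean, so overlapping regions carry correlated expression and
region labels are transform-consistent (a perfect clustering of the truth
yields overlap agreement 1.0).

Spot pixel coordinates carry sub-pitch jitter (uniform per axis, default
pitch/10, always < pitch/4) so that transformed spot centroids do not
cleanly coincide at overlaps, while nominal positions — and hence ground
truth — remain exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .geometry import AffineTransform, GroupPlan, compute_rescale_factors
from .imaging import compose_canvas
from .spaceranger_io import (
    CaptureArea,
    CountMatrix,
    ScaleFactors,
    write_count_matrix,
    write_scalefactors,
    write_tissue_positions,
)

__all__ = [
    "GENES",
    "FixtureSpec",
    "GroundTruth",
    "GroupFixture",
    "make_capture_area_fixture",
    "make_group_fixture",
    "true_overlap_pairs",
]

#: gene panel: two markers per region plus two housekeeping genes
GENES = ["WM_MARK1", "WM_MARK2", "CTX_MARK1", "CTX_MARK2", "HOUSE1", "HOUSE2"]

_SQRT3_2 = np.sqrt(3.0) / 2.0


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study design.

    Defaults describe a standard Visium capture area (78 × 128 array, 55 µm
    spots 100 µm apart) and the three-area group layout: areas 1 and 2
    overlap by ``overlap_fraction`` of their width, area 3 sits
    ``gap_pitches`` spot pitches beyond area 2 and is rotated 180°.
    """

    n_rows: int = 78
    n_cols: int = 128
    spot_diameter_fullres: float = 55.0
    tissue_hires_scalef: float = 0.2
    overlap_fraction: float = 0.5
    gap_pitches: float = 2.0
    rotations_deg: tuple[float, ...] = (0.0, 0.0, 180.0)
    #: per-area library-depth multiplier on all Poisson means; drives the
    #: mean-UMI ranking used by overlap exclusion
    depth_factors: tuple[float, ...] = (1.1, 0.9, 1.0)
    #: per-axis uniform jitter amplitude as a fraction of the spot pitch
    jitter_frac: float = 0.1
    marker_mean_in_region: float = 2.0
    marker_mean_out_region: float = 0.1
    housekeeping_mean: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 2:
            raise ValueError(f"invalid array dimensions {self.n_rows}x{self.n_cols}")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError(f"overlap_fraction must be in [0,1], got {self.overlap_fraction}")
        if self.gap_pitches < 0:
            raise ValueError("negative gap between adjacent areas")
        if not 0.0 <= self.jitter_frac < 0.25:
            raise ValueError("jitter_frac must be < 0.25 (sub-pitch jitter)")

    @property
    def pitch_px(self) -> float:
        """Inter-spot pitch in fullres pixels (100 µm over 55 µm diameter)."""
        return self.spot_diameter_fullres * (100.0 / 55.0)


@dataclass
class GroundTruth:
    """Planted truth for one group fixture."""

    transforms: dict[str, list[list[float]]]
    overlap_pairs: list[tuple[str, str]]
    region_labels: dict[str, str]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(
                {
                    "transforms": self.transforms,
                    "overlap_pairs": [list(p) for p in self.overlap_pairs],
                    "region_labels": self.region_labels,
                },
                fh,
            )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            transforms=raw["transforms"],
            overlap_pairs=[tuple(p) for p in raw["overlap_pairs"]],
            region_labels=raw["region_labels"],
        )


@dataclass
class GroupFixture:
    """Paths and truth for a generated group of capture areas."""

    root: Path
    area_ids: list[str]
    area_dirs: list[Path]
    transform_xml: Path
    sample_info: Path
    composite_image: Path
    ground_truth: GroundTruth
    areas: list[CaptureArea] = field(default_factory=list, repr=False)
    plan: GroupPlan | None = field(default=None, repr=False)


def true_overlap_pairs(truth: GroundTruth) -> list[tuple[str, str]]:
    """Cross-area spot pairs whose true positions coincide (within pitch/2)."""
    return list(truth.overlap_pairs)


def _nominal_grid(spec: FixtureSpec) -> pd.DataFrame:
    """Local fullres coordinates of the equal-parity hexagonal spot grid."""
    p = spec.pitch_px
    margin = p
    rows, cols = np.meshgrid(
        np.arange(spec.n_rows), np.arange(spec.n_cols), indexing="ij"
    )
    keep = (rows % 2) == (cols % 2)
    rows, cols = rows[keep], cols[keep]
    return pd.DataFrame(
        {
            "array_row": rows,
            "array_col": cols,
            "x": margin + cols * (p / 2.0),
            "y": margin + rows * (p * _SQRT3_2),
        }
    )


def _canvas_fullres_dims(spec: FixtureSpec) -> tuple[float, float]:
    p = spec.pitch_px
    width = 2 * p + (spec.n_cols - 1) * (p / 2.0)
    height = 2 * p + (spec.n_rows - 1) * (p * _SQRT3_2)
    return width, height


def _rotation(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    return np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])


def _draw_counts(
    spec: FixtureSpec, labels: np.ndarray, depth: float, rng: np.random.Generator
) -> sp.csr_matrix:
    """Poisson counts, genes × spots, from per-region mean vectors."""
    hi, lo, hk = (
        spec.marker_mean_in_region,
        spec.marker_mean_out_region,
        spec.housekeeping_mean,
    )
    gene_means = {
        "WM_MARK1": (hi, lo),
        "WM_MARK2": (hi, lo),
        "CTX_MARK1": (lo, hi),
        "CTX_MARK2": (lo, hi),
        "HOUSE1": (hk, hk),
        "HOUSE2": (hk, hk),
    }
    wm = labels == "WM"
    means = np.empty((len(GENES), labels.size))
    for i, g in enumerate(GENES):
        mu_wm, mu_ctx = gene_means[g]
        means[i] = np.where(wm, mu_wm, mu_ctx)
    return sp.csr_matrix(rng.poisson(means * depth).astype(np.int64))


def _paint_image(
    spec: FixtureSpec, grid: pd.DataFrame, labels: np.ndarray
) -> np.ndarray:
    """Hires PNG content: shaded spot disks on white plus dark landmark blobs."""
    h = spec.tissue_hires_scalef
    width, height = _canvas_fullres_dims(spec)
    img = np.full((int(round(height * h)), int(round(width * h)), 3), 235, dtype=np.uint8)
    cx = (grid["x"].to_numpy() * h).round().astype(int)
    cy = (grid["y"].to_numpy() * h).round().astype(int)
    rad = max(1, int(round(spec.spot_diameter_fullres * h / 2)))
    colors = np.where(labels[:, None] == "WM", (150, 150, 200), (220, 180, 160)).astype(np.uint8)
    yy, xx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    disk = (yy**2 + xx**2) <= rad**2
    for x, y, color in zip(cx, cy, colors):
        y0, y1 = max(y - rad, 0), min(y + rad + 1, img.shape[0])
        x0, x1 = max(x - rad, 0), min(x + rad + 1, img.shape[1])
        d = disk[(y0 - (y - rad)) : (y1 - (y - rad)), (x0 - (x - rad)) : (x1 - (x - rad))]
        img[y0:y1, x0:x1][d] = color
    # three dark landmark blobs at fixed array positions, for visual checks
    marks = [(4, 4), (4, spec.n_cols - 2), (spec.n_rows - 2, 4)]
    p = spec.pitch_px
    big = max(2, int(round(2 * spec.spot_diameter_fullres * h)))
    yy, xx = np.mgrid[-big : big + 1, -big : big + 1]
    blob = (yy**2 + xx**2) <= big**2
    for r, c in marks:
        c = min(max(c + ((r % 2) - (c % 2)) % 2, 0), spec.n_cols - 1)  # repair parity
        x = int(round((p + c * p / 2.0) * h))
        y = int(round((p + r * p * _SQRT3_2) * h))
        y0, y1 = max(y - big, 0), min(y + big + 1, img.shape[0])
        x0, x1 = max(x - big, 0), min(x + big + 1, img.shape[1])
        b = blob[(y0 - (y - big)) : (y1 - (y - big)), (x0 - (x - big)) : (x1 - (x - big))]
        img[y0:y1, x0:x1][b] = (40, 40, 40)
    return img


def _build_area(
    spec: FixtureSpec,
    area_id: str,
    area_index: int,
    offset: tuple[float, float],
    rotation_deg: float,
    threshold_x: float,
    depth: float,
) -> tuple[CaptureArea, pd.DataFrame, AffineTransform]:
    """One capture area sampled from the global tissue field.

    Returns the in-memory area, a per-spot table with nominal global
    coordinates and region labels, and the planted affine (in the
    rescaled-hires pixel space stitching operates in).
    """
    rng = np.random.default_rng([spec.seed, area_index])
    grid = _nominal_grid(spec)
    p = spec.pitch_px
    width, height = _canvas_fullres_dims(spec)
    center = np.array([width / 2.0, height / 2.0])
    R = _rotation(rotation_deg)
    local = grid[["x", "y"]].to_numpy()
    nominal_global = (local - center) @ R.T + center + np.asarray(offset)
    labels = np.where(nominal_global[:, 0] < threshold_x, "WM", "CTX")

    jitter = rng.uniform(-spec.jitter_frac * p, spec.jitter_frac * p, size=local.shape)
    pixel = local + jitter

    barcodes = [
        f"SPOT{r:03d}X{c:03d}-1"
        for r, c in zip(grid["array_row"], grid["array_col"])
    ]
    spots = pd.DataFrame(
        {
            "barcode": barcodes,
            "in_tissue": 1,
            "array_row": grid["array_row"].to_numpy(),
            "array_col": grid["array_col"].to_numpy(),
            "pxl_row_in_fullres": pixel[:, 1],
            "pxl_col_in_fullres": pixel[:, 0],
        }
    )
    counts = CountMatrix(
        genes=list(GENES), barcodes=barcodes, counts=_draw_counts(spec, labels, depth, rng)
    )
    sf = ScaleFactors(
        spot_diameter_fullres=spec.spot_diameter_fullres,
        tissue_hires_scalef=spec.tissue_hires_scalef,
        tissue_lowres_scalef=spec.tissue_hires_scalef * 600.0 / 2000.0,
        fiducial_diameter_fullres=spec.spot_diameter_fullres * (85.0 / 55.0),
    )
    image = _paint_image(spec, grid, labels)
    area = CaptureArea(
        area_id=area_id, spots=spots, scalefactors=sf, hires_image=image, counts=counts
    )
    # planted transform: hires_global = R · (h·local) + h·((I−R)·center + offset)
    h = spec.tissue_hires_scalef
    translation = h * ((np.eye(2) - R) @ center + np.asarray(offset))
    matrix = np.column_stack([R, translation])
    truth_table = pd.DataFrame(
        {
            "spot_id": [b + "_" + area_id for b in barcodes],
            "area_id": area_id,
            "gx": nominal_global[:, 0],
            "gy": nominal_global[:, 1],
            "label": labels,
        }
    )
    return area, truth_table, AffineTransform(matrix)


def _write_area_dir(area: CaptureArea, out_dir: Path) -> Path:
    spatial = out_dir / "spatial"
    spatial.mkdir(parents=True, exist_ok=True)
    write_tissue_positions(area.spots, spatial / "tissue_positions.csv")
    write_scalefactors(area.scalefactors, spatial / "scalefactors_json.json")
    if area.hires_image is not None:
        iio.imwrite(spatial / "tissue_hires_image.png", area.hires_image)
    if area.counts is not None:
        write_count_matrix(area.counts, out_dir / "filtered_feature_bc_matrix")
    return out_dir


def make_capture_area_fixture(
    spec: FixtureSpec, area_id: str, out_dir: str | Path
) -> CaptureArea:
    """Generate one standalone capture area and write its bundle to disk.

    The region boundary runs vertically through the middle of the area.
    Deterministic: the same spec (including seed) yields byte-identical
    files.
    """
    out_dir = Path(out_dir)
    width, _ = _canvas_fullres_dims(spec)
    area, _, _ = _build_area(
        spec,
        area_id,
        area_index=0,
        offset=(0.0, 0.0),
        rotation_deg=0.0,
        threshold_x=width / 2.0 + spec.pitch_px / 4.0,
        depth=1.0,
    )
    _write_area_dir(area, out_dir)
    return area


def _overlap_offset_cols(spec: FixtureSpec) -> int:
    """Horizontal offset of area 2, in array columns (kept even so nominal
    lattice positions of the two areas coincide exactly in the overlap)."""
    return int(round((1.0 - spec.overlap_fraction) * spec.n_cols / 2.0)) * 2


def make_group_fixture(
    spec: FixtureSpec,
    out_dir: str | Path,
    area_ids: tuple[str, ...] = ("A1", "B1", "C1"),
) -> GroupFixture:
    """Generate the three-area group: A1/B1 overlapping, C1 across a gap.

    Writes one SpaceRanger-style directory per area, the planted transforms
    as TrakEM2-style XML, a ``sample_info.csv``, the stitched composite PNG,
    and ``ground_truth.json`` listing exact overlapping spot pairs and
    per-spot region labels.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p = spec.pitch_px
    width, _ = _canvas_fullres_dims(spec)
    off_b = _overlap_offset_cols(spec) * p / 2.0
    off_c = off_b + width + spec.gap_pitches * p
    offsets = [(0.0, 0.0), (off_b, 0.0), (off_c, 0.0)]
    rotations = list(spec.rotations_deg) + [0.0] * max(0, len(area_ids) - len(spec.rotations_deg))
    depths = list(spec.depth_factors) + [1.0] * max(0, len(area_ids) - len(spec.depth_factors))
    threshold_x = 0.35 * (off_b + width) + p / 4.0

    areas: list[CaptureArea] = []
    truth_tables = []
    transforms: dict[str, AffineTransform] = {}
    area_dirs = []
    for i, area_id in enumerate(area_ids):
        area, truth_table, transform = _build_area(
            spec, area_id, i, offsets[i], rotations[i], threshold_x, depths[i]
        )
        areas.append(area)
        truth_tables.append(truth_table)
        transforms[area_id] = transform
        area_dirs.append(_write_area_dir(area, out_dir / area_id))

    xml_path = _write_transform_xml(transforms, out_dir / "transforms.xml")
    sample_info = out_dir / "sample_info.csv"
    pd.DataFrame(
        {
            "group": "group1",
            "capture_area": list(area_ids),
            "spaceranger_dir": [str(d) for d in area_dirs],
            "image_path": [str(d / "spatial" / "tissue_hires_image.png") for d in area_dirs],
        }
    ).to_csv(sample_info, index=False)

    plan = GroupPlan(
        group_id="group1",
        members=list(area_ids),
        transforms=transforms,
        rescale=compute_rescale_factors({a.area_id: a.scalefactors for a in areas}),
    )
    composite = compose_canvas(areas, plan)
    composite_path = out_dir / "stitched_composite.png"
    iio.imwrite(composite_path, composite)

    truth = _ground_truth(pd.concat(truth_tables, ignore_index=True), transforms, p)
    truth.to_json(out_dir / "ground_truth.json")
    return GroupFixture(
        root=out_dir,
        area_ids=list(area_ids),
        area_dirs=area_dirs,
        transform_xml=xml_path,
        sample_info=sample_info,
        composite_image=composite_path,
        ground_truth=truth,
        areas=areas,
        plan=plan,
    )


def _ground_truth(
    truth_table: pd.DataFrame, transforms: dict[str, AffineTransform], pitch: float
) -> GroundTruth:
    from scipy.spatial import cKDTree

    xy = truth_table[["gx", "gy"]].to_numpy()
    tree = cKDTree(xy)
    pairs = []
    for i, j in sorted(tree.query_pairs(pitch / 2.0)):
        if truth_table.at[i, "area_id"] != truth_table.at[j, "area_id"]:
            pairs.append((truth_table.at[i, "spot_id"], truth_table.at[j, "spot_id"]))
    return GroundTruth(
        transforms={a: t.matrix.tolist() for a, t in transforms.items()},
        overlap_pairs=pairs,
        region_labels=dict(zip(truth_table["spot_id"], truth_table["label"])),
    )


def _write_transform_xml(transforms: dict[str, AffineTransform], path: Path) -> Path:
    lines = ["<?xml version=\"1.0\"?>", "<trakem2>"]
    for area_id, t in transforms.items():
        a, c, tx = (float(v) for v in t.matrix[0])
        b, d, ty = (float(v) for v in t.matrix[1])
        lines.append(
            f'  <t2_patch title="{area_id}" '
            f'transform="matrix({a!r},{b!r},{c!r},{d!r},{tx!r},{ty!r})"/>'
        )
    lines.append("</trakem2>")
    path.write_text("\n".join(lines) + "\n")
    return path
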