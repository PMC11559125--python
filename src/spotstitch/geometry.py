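"""Rescale factors and affine coordinate transforms for stitching.

Capture areas imaged at different magnifications do not share a physical
pixel scale.  Before images can be stitched on one canvas, each area ``i``
is rescaled by

    s_i = (max_j d_j)(max_j h_j) / (d_i h_i)

where ``d_i`` is the spot diameter in fullres pixels and ``h_i`` the hires
scale factor, so that a pixel of every rescaled hires image covers the same
physical distance.  The stitching step (performed interactively in Fiji)
yields one rigid affine transform per area in that rescaled-hires pixel
space.  To map a spot's fullres coordinates into the group coordinate
system we lift them into the rescaled-hires space (multiply by h_i·s_i),
apply the area's affine, and project back by dividing by h_ref·s_ref, where
the reference area is the one with the coarsest physical resolution
(maximal d·h).  The combined per-area scalar h_i·s_i/(h_ref·s_ref) is the
``intra_group_scalar``; it guarantees identical distances-per-pixel across
all areas of a group.
"""

from __future__ import annotations

import re
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .spaceranger_io import CaptureArea, ScaleFactors

__all__ = [
    "AffineTransform",
    "RescalePlan",
    "GroupPlan",
    "compute_rescale_factors",
    "parse_transform_xml",
    "parse_transform_table",
    "parse_transforms",
    "apply_affine",
    "transform_group_coords",
]


@dataclass
class AffineTransform:
    """A 2×3 affine matrix ``[[a, c, tx], [b, d, ty]]`` on column (x, y, 1).

    For rigid transforms the linear part has |det| ≈ 1; a determinant
    outside [0.99, 1.01] triggers a warning (Fiji users may apply slight
    scaling) but is not an error.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise ValueError(f"affine matrix must be 2x3, got {self.matrix.shape}")
        det = abs(np.linalg.det(self.matrix[:, :2]))
        if det == 0:
            raise ValueError("affine linear part is singular")
        if not (0.99 <= det <= 1.01):
            warnings.warn(
                f"affine determinant magnitude {det:.4f} outside [0.99, 1.01]; "
                "transform is not rigid",
                stacklevel=2,
            )

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @classmethod
    def from_params(cls, a: float, b: float, c: float, d: float, tx: float, ty: float):
        """TrakEM2 parameter order: column-major linear part then translation."""
        return cls(np.array([[a, c, tx], [b, d, ty]], dtype=float))

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return apply_affine(points, self)


def apply_affine(points: np.ndarray, transform: AffineTransform) -> np.ndarray:
    """Apply an affine transform to an n×2 array of (x, y) points."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, 2)
    pts = np.atleast_2d(pts)
    if pts.shape[1] != 2:
        raise ValueError(f"points must be n x 2, got {pts.shape}")
    linear = transform.matrix[:, :2]
    translation = transform.matrix[:, 2]
    return pts @ linear.T + translation


@dataclass
class RescalePlan:
    """Per-area rescale factors for one group.

    ``s`` holds the image rescale factor s_i, ``intra_group_scalar`` the
    coordinate scalar h_i·s_i/(h_ref·s_ref), and ``reference_area`` the area
    whose fullres pixel scale defines the group coordinate space.
    """

    s: dict[str, float]
    intra_group_scalar: dict[str, float]
    reference_area: str
    lift: dict[str, float] = field(default_factory=dict)  # h_i * s_i per area


def compute_rescale_factors(
    scalefactors: Mapping[str, ScaleFactors], use_product_max: bool = False
) -> RescalePlan:
    """Compute the per-area rescale factors s_i for a group.

    By default the numerator is (max over areas of d) × (max over areas of
    h), evaluated independently.  With ``use_product_max`` the numerator is
    max over areas of (d·h) instead; the two differ only when the maxima of
    d and h are achieved by different areas, in which case the default can
    yield s_i > 1 for every area.

    The reference area is the one with maximal d·h (coarsest physical
    resolution); its rescaled-hires pixel scale defines the group fullres
    coordinate space.
    """
    if not scalefactors:
        raise ValueError("empty group: no scale factors supplied")
    d = {a: sf.spot_diameter_fullres for a, sf in scalefactors.items()}
    h = {a: sf.tissue_hires_scalef for a, sf in scalefactors.items()}
    if use_product_max:
        numerator = max(d[a] * h[a] for a in d)
    else:
        numerator = max(d.values()) * max(h.values())
    s = {a: numerator / (d[a] * h[a]) for a in d}
    reference = max(d, key=lambda a: (d[a] * h[a], a))
    lift = {a: h[a] * s[a] for a in d}
    ref_lift = lift[reference]
    scalar = {a: lift[a] / ref_lift for a in d}
    return RescalePlan(s=s, intra_group_scalar=scalar, reference_area=reference, lift=lift)


@dataclass
class GroupPlan:
    """Everything needed to stitch one group of capture areas."""

    group_id: str
    members: list[str]
    transforms: dict[str, AffineTransform]
    rescale: RescalePlan

    def __post_init__(self) -> None:
        for member in self.members:
            if member not in self.transforms:
                raise ValueError(f"no transform for capture area {member}")
            if member not in self.rescale.s:
                raise ValueError(f"no rescale entry for capture area {member}")


_MATRIX_RE = re.compile(
    r"matrix\(\s*([^,)\s]+)\s*,\s*([^,)\s]+)\s*,\s*([^,)\s]+)\s*,"
    r"\s*([^,)\s]+)\s*,\s*([^,)\s]+)\s*,\s*([^,)\s]+)\s*\)"
)


def _parse_matrix_string(text: str) -> AffineTransform:
    m = _MATRIX_RE.search(text)
    if m is None:
        raise ValueError(f"malformed transform string: {text!r}")
    a, b, c, d, tx, ty = (float(g) for g in m.groups())
    return AffineTransform.from_params(a, b, c, d, tx, ty)


def parse_transform_xml(
    path: str | Path, members: Sequence[str]
) -> dict[str, AffineTransform]:
    """Parse per-area rigid affine transforms from a TrakEM2-style XML file.

    Any element carrying a ``file_path`` or ``title`` attribute whose value
    contains a member's area id, together with a ``transform`` or ``data``
    attribute of the form ``matrix(a,b,c,d,tx,ty)``, supplies that area's
    transform.  Parameter order is TrakEM2's: column-major linear part
    (a, b, c, d) then translation (tx, ty), i.e. the matrix
    ``[[a, c, tx], [b, d, ty]]``.
    """
    tree = ET.parse(path)
    found: dict[str, AffineTransform] = {}
    for element in tree.iter():
        name = element.get("file_path") or element.get("title")
        spec = element.get("transform") or element.get("data")
        if name is None or spec is None:
            continue
        for member in members:
            if member in name:
                found[member] = _parse_matrix_string(spec)
    missing = [m for m in members if m not in found]
    if missing:
        raise ValueError(f"no transform entry in {path} for area(s): {', '.join(missing)}")
    return found


def parse_transform_table(
    path: str | Path, members: Sequence[str]
) -> dict[str, AffineTransform]:
    """Parse the plain-text fallback: one ``area_id a b c d tx ty`` per line.

    Blank lines and ``#`` comments are ignored.
    """
    found: dict[str, AffineTransform] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"{path}:{lineno}: expected 7 fields, got {len(parts)}")
        area, *values = parts
        a, b, c, d, tx, ty = (float(v) for v in values)
        found[area] = AffineTransform.from_params(a, b, c, d, tx, ty)
    missing = [m for m in members if m not in found]
    if missing:
        raise ValueError(f"no transform entry in {path} for area(s): {', '.join(missing)}")
    return {m: found[m] for m in members}


def parse_transforms(path: str | Path, members: Sequence[str]) -> dict[str, AffineTransform]:
    """Dispatch on file content: XML document or plain transform table."""
    text = Path(path).read_text().lstrip()
    if text.startswith("<"):
        return parse_transform_xml(path, members)
    return parse_transform_table(path, members)


def transform_group_coords(
    areas: Sequence[CaptureArea],
    plan: GroupPlan,
    in_tissue_only: bool = True,
) -> pd.DataFrame:
    """Map every spot's fullres pixel coordinates into the group space.

    For each area: fullres (x, y) × h_i·s_i  →  affine  →  ÷ h_ref·s_ref.
    The output columns are ``area_id, barcode, pxl_row_stitched,
    pxl_col_stitched``; distances per pixel are identical across areas.
    """
    frames = []
    for area in areas:
        if area.area_id not in plan.members:
            raise ValueError(f"capture area {area.area_id} not in group plan")
        spots = area.in_tissue_spots() if in_tissue_only else area.spots
        lift = plan.rescale.lift[area.area_id]
        project = plan.rescale.lift[plan.rescale.reference_area]
        xy = spots[["pxl_col_in_fullres", "pxl_row_in_fullres"]].to_numpy(dtype=float)
        stitched = apply_affine(xy * lift, plan.transforms[area.area_id]) / project
        frames.append(
            pd.DataFrame(
                {
                    "area_id": area.area_id,
                    "barcode": spots["barcode"].to_numpy(),
                    "pxl_row_stitched": stitched[:, 1],
                    "pxl_col_stitched": stitched[:, 0],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
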