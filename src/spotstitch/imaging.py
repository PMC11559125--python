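"""Image rescaling and the group-level low-resolution bundle.

The stitched composite image lives in the rescaled-hires pixel space the
stitching tool operated in.  For the group-level sample it is downscaled to
a lowres image (default 1,200 px longest dimension, sized for a 2×2 block
of capture areas at SpaceRanger's 600 px lowres cap) and paired with scale
factors that relate lowres pixels to the group fullres coordinate space.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from skimage.transform import resize

from .geometry import GroupPlan, apply_affine
from .spaceranger_io import CaptureArea, ScaleFactors

__all__ = [
    "DEFAULT_TARGET_LONGEST",
    "rescale_image",
    "make_lowres_bundle",
    "compose_canvas",
]

#: default longest dimension of the group lowres image:
#: 600 px (SpaceRanger lowres cap) × 2 areas, for a square 2×2 group
DEFAULT_TARGET_LONGEST = 1200


def _as_uint8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def rescale_image(img: np.ndarray, s: float) -> np.ndarray:
    """Uniformly rescale an image by factor ``s`` with bilinear resampling.

    Output dimensions are round(height·s) × round(width·s).
    """
    if not s > 0:
        raise ValueError(f"scale factor must be positive, got {s}")
    img = np.asarray(img)
    new_h = int(round(img.shape[0] * s))
    new_w = int(round(img.shape[1] * s))
    if (new_h, new_w) == img.shape[:2]:
        return img.copy()
    out_shape = (new_h, new_w) + img.shape[2:]
    resized = resize(img, out_shape, order=1, preserve_range=True, anti_aliasing=False)
    return _as_uint8(resized) if img.dtype == np.uint8 else resized


def make_lowres_bundle(
    stitched_img: np.ndarray,
    plan: GroupPlan,
    scalefactors_ref: ScaleFactors,
    target_longest: int = DEFAULT_TARGET_LONGEST,
) -> tuple[np.ndarray, ScaleFactors]:
    """Downscale the stitched composite and derive coherent scale factors.

    Parameters
    ----------
    stitched_img
        Composite image in rescaled-hires pixel space.
    plan
        Group plan; supplies h_ref·s_ref, the factor relating the composite's
        pixels to the group fullres coordinate space.
    scalefactors_ref
        Reference area's scale factors; spot and fiducial diameters are
        copied from here.
    target_longest
        Longest dimension of the output image, exactly.

    Returns
    -------
    (lowres image, ScaleFactors) where ``tissue_lowres_scalef`` maps group
    fullres coordinates onto lowres pixels and ``tissue_hires_scalef`` maps
    them onto the composite's pixels.
    """
    stitched_img = np.asarray(stitched_img)
    h, w = stitched_img.shape[:2]
    if h < 1 or w < 1:
        raise ValueError("degenerate stitched image with zero extent")
    scale = target_longest / max(h, w)
    if max(h, w) == h:
        out_shape = (target_longest, max(1, int(round(w * scale))))
    else:
        out_shape = (max(1, int(round(h * scale))), target_longest)
    if out_shape == stitched_img.shape[:2]:
        lowres = stitched_img.copy()
    else:
        lowres = _as_uint8(
            resize(
                stitched_img,
                out_shape + stitched_img.shape[2:],
                order=1,
                preserve_range=True,
                anti_aliasing=scale < 1,
            )
        )
    # composite pixels per group-fullres pixel
    hires_scalef = plan.rescale.lift[plan.rescale.reference_area]
    lowres_scalef = hires_scalef * scale
    sf = ScaleFactors(
        spot_diameter_fullres=scalefactors_ref.spot_diameter_fullres,
        tissue_hires_scalef=hires_scalef,
        tissue_lowres_scalef=lowres_scalef,
        fiducial_diameter_fullres=scalefactors_ref.fiducial_diameter_fullres,
    )
    return lowres, sf


def compose_canvas(
    areas: Sequence[CaptureArea],
    plan: GroupPlan,
    margin: int = 0,
) -> np.ndarray:
    """Paste transformed per-area hires images onto one canvas.

    A synthetic stand-in for the stitching tool's composite output: each
    area's hires image is rescaled by s_i, its corner coordinates are mapped
    through the area's affine, and pixels are pasted last-wins (no blending).
    Transforms are assumed rigid up to axis-aligned placement; rotated areas
    are resampled via inverse mapping of the canvas block they cover.
    """
    from .geometry import AffineTransform  # local to avoid cycle confusion

    placements = []
    min_x = min_y = np.inf
    max_x = max_y = -np.inf
    for area in areas:
        if area.hires_image is None:
            raise ValueError(f"{area.area_id}: no hires image to compose")
        img = rescale_image(area.hires_image, plan.rescale.s[area.area_id])
        h, w = img.shape[:2]
        corners = np.array([[0, 0], [w, 0], [0, h], [w, h]], dtype=float)
        tc = apply_affine(corners, plan.transforms[area.area_id])
        placements.append((img, plan.transforms[area.area_id]))
        min_x = min(min_x, tc[:, 0].min())
        min_y = min(min_y, tc[:, 1].min())
        max_x = max(max_x, tc[:, 0].max())
        max_y = max(max_y, tc[:, 1].max())
    width = int(np.ceil(max_x)) + margin
    height = int(np.ceil(max_y)) + margin
    canvas = np.zeros((max(height, 1), max(width, 1), 3), dtype=np.uint8)
    for img, transform in placements:
        h, w = img.shape[:2]
        corners = np.array([[0, 0], [w, 0], [0, h], [w, h]], dtype=float)
        tc = apply_affine(corners, transform)
        x0 = max(int(np.floor(tc[:, 0].min())), 0)
        y0 = max(int(np.floor(tc[:, 1].min())), 0)
        x1 = min(int(np.ceil(tc[:, 0].max())), canvas.shape[1])
        y1 = min(int(np.ceil(tc[:, 1].max())), canvas.shape[0])
        if x1 <= x0 or y1 <= y0:
            continue
        # inverse-map each canvas pixel in the block to source coordinates
        linear = transform.matrix[:, :2]
        translation = transform.matrix[:, 2]
        inv = np.linalg.inv(linear)
        ys, xs = np.mgrid[y0:y1, x0:x1]
        pts = np.stack([xs.ravel() + 0.5, ys.ravel() + 0.5], axis=1) - translation
        src = pts @ inv.T - 0.5
        sx = np.rint(src[:, 0]).astype(int)
        sy = np.rint(src[:, 1]).astype(int)
        valid = (sx >= 0) & (sx < w) & (sy >= 0) & (sy < h)
        block = canvas[y0:y1, x0:x1].reshape(-1, 3)
        if img.ndim == 2:
            img = np.repeat(img[:, :, None], 3, axis=2)
        block[valid] = img[sy[valid], sx[valid], :3]
        canvas[y0:y1, x0:x1] = block.reshape(y1 - y0, x1 - x0, 3)
    return canvas
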