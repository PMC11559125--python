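"""Assemble group-level stitched samples and handle overlapping spots.

A stitched sample concatenates the spots and counts of all member capture
areas (nothing is dropped, even where areas overlap), carries transformed
pixel coordinates and re-derived hexagonal array coordinates, and flags
which spots to hide in plots where several areas contest one array
position.  Two spots "overlap" iff they are assigned the same artificial
array position — the definition downstream hex-grid clustering actually
experiences; a distance-based alternative (< pitch/2 in pixel space) is
available behind a flag.

For methods that cannot tolerate multi-occupancy, :func:`merge_overlapping`
collapses each occupied array position to a single spot whose counts are
the elementwise sum of the contributors.  :func:`overlap_label_agreement`
scores a clustering by the fraction of cross-area spot pairs at shared
positions that received the same label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import hexarray
from .geometry import GroupPlan, transform_group_coords
from .imaging import DEFAULT_TARGET_LONGEST, compose_canvas, make_lowres_bundle
from .spaceranger_io import CaptureArea, CountMatrix, ScaleFactors

__all__ = [
    "StitchedSample",
    "build_stitched_sample",
    "flag_exclude_overlapping",
    "merge_overlapping",
    "overlap_label_agreement",
    "load_stitched_sample",
]


@dataclass
class StitchedSample:
    """The group-level result of stitching.

    ``spots`` has one row per spot of every member area (barcodes suffixed
    with ``_<area_id>`` for global uniqueness) with columns: ``barcode``,
    ``in_tissue``, ``array_row``, ``array_col`` (re-derived, group-wide),
    ``pxl_row_in_fullres``, ``pxl_col_in_fullres`` (transformed),
    ``capture_area``, ``exclude_overlapping``, ``sum_umi`` and
    ``distance_to_centroid``.
    """

    group_id: str
    spots: pd.DataFrame
    counts: CountMatrix | None
    scalefactors: ScaleFactors
    lowres_image: np.ndarray | None = None
    lattice: hexarray.HexLattice | None = None
    merged_from: pd.Series | None = field(default=None, repr=False)

    def overlap_pairs(self) -> pd.DataFrame:
        """Unordered cross-area spot pairs sharing an array position."""
        return _cross_area_pairs(self.spots)


def _concat_counts(areas: Sequence[CaptureArea], spot_order: pd.DataFrame) -> CountMatrix:
    """Concatenate member count matrices over the union of gene lists.

    Genes absent from an area are zero-filled.  Column order follows
    ``spot_order`` (area_id, barcode), and barcodes are suffixed with the
    capture-area id.
    """
    gene_union: list[str] = []
    seen: set[str] = set()
    for area in areas:
        for g in area.counts.genes:
            if g not in seen:
                seen.add(g)
                gene_union.append(g)
    gene_index = {g: i for i, g in enumerate(gene_union)}
    blocks = []
    barcodes: list[str] = []
    by_id = {a.area_id: a for a in areas}
    for area_id, group in spot_order.groupby("capture_area", sort=False):
        area = by_id[area_id]
        cm = area.counts
        col_of = {b: j for j, b in enumerate(cm.barcodes)}
        cols = [col_of[b] for b in group["orig_barcode"]]
        block = cm.counts.tocsc()[:, cols]
        rows = np.array([gene_index[g] for g in cm.genes])
        lifted = sp.coo_matrix(block)
        lifted = sp.coo_matrix(
            (lifted.data, (rows[lifted.row], lifted.col)),
            shape=(len(gene_union), block.shape[1]),
        )
        blocks.append(lifted.tocsr())
        barcodes.extend(group["barcode"].tolist())
    counts = sp.hstack(blocks, format="csr") if blocks else sp.csr_matrix((0, 0))
    return CountMatrix(genes=gene_union, barcodes=barcodes, counts=counts)


def flag_exclude_overlapping(
    spots: pd.DataFrame, distance_overlap: bool = False, pitch_px: float | None = None
) -> pd.Series:
    """Mark spots to hide at array positions contested by several areas.

    Capture areas are ranked by mean UMI per spot over the whole area; at
    every contested position the spots of the highest-ranked present area
    keep ``False`` and all others get ``True``.  Uncontested spots are
    ``False``.  Exact mean-UMI ties retain the lexicographically smaller
    area id.

    With ``distance_overlap`` the contest is defined by pixel distance
    (< pitch/2 between cross-area spots) instead of array-position identity.
    """
    mean_umi = spots.groupby("capture_area")["sum_umi"].mean()
    # rank: higher mean wins; ties -> lexicographically smaller id wins
    order = sorted(mean_umi.index, key=lambda a: (-mean_umi[a], a))
    rank = {a: i for i, a in enumerate(order)}
    exclude = pd.Series(False, index=spots.index)
    if distance_overlap:
        if pitch_px is None:
            raise ValueError("distance_overlap requires pitch_px")
        pairs = _cross_area_pairs_by_distance(spots, pitch_px / 2.0)
        contested_groups = _connected_components(spots, pairs)
    else:
        pos = spots.groupby(["array_row", "array_col"])
        contested_groups = [
            idx for _, idx in pos.groups.items()
            if spots.loc[idx, "capture_area"].nunique() > 1
        ]
    for idx in contested_groups:
        areas_here = spots.loc[idx, "capture_area"]
        winner = min(areas_here.unique(), key=lambda a: rank[a])
        exclude.loc[idx[areas_here != winner]] = True
    return exclude


def _connected_components(spots: pd.DataFrame, pairs: pd.DataFrame) -> list[pd.Index]:
    """Group spot indices linked by overlap pairs (for the distance mode)."""
    parent: dict = {}

    def find(x):
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    for i, j in zip(pairs["index_a"], pairs["index_b"]):
        parent.setdefault(i, i)
        parent.setdefault(j, j)
        parent[find(i)] = find(j)
    groups: dict = {}
    for x in parent:
        groups.setdefault(find(x), []).append(x)
    return [pd.Index(v) for v in groups.values() if len(v) > 1]


def _cross_area_pairs(spots: pd.DataFrame) -> pd.DataFrame:
    """All unordered cross-area pairs sharing one (array_row, array_col)."""
    rows = []
    for (r, c), idx in spots.groupby(["array_row", "array_col"]).groups.items():
        if len(idx) < 2:
            continue
        sub = spots.loc[idx]
        for i, j in combinations(idx, 2):
            if sub.at[i, "capture_area"] != sub.at[j, "capture_area"]:
                rows.append((i, j, r, c))
    return pd.DataFrame(rows, columns=["index_a", "index_b", "array_row", "array_col"])


def _cross_area_pairs_by_distance(spots: pd.DataFrame, radius: float) -> pd.DataFrame:
    from scipy.spatial import cKDTree

    xy = spots[["pxl_col_in_fullres", "pxl_row_in_fullres"]].to_numpy()
    tree = cKDTree(xy)
    rows = []
    for i, j in tree.query_pairs(radius):
        a, b = spots.index[i], spots.index[j]
        if spots.at[a, "capture_area"] != spots.at[b, "capture_area"]:
            rows.append((a, b, -1, -1))
    return pd.DataFrame(rows, columns=["index_a", "index_b", "array_row", "array_col"])


def build_stitched_sample(
    areas: Sequence[CaptureArea],
    plan: GroupPlan,
    stitched_img: np.ndarray | None = None,
    target_longest: int = DEFAULT_TARGET_LONGEST,
    in_tissue_only: bool = True,
    spot_diameter_um: float = hexarray.SPOT_DIAMETER_UM,
    distance_overlap: bool = False,
) -> StitchedSample:
    """Build the group-level stitched sample.

    Steps: transform all spot coordinates into the group fullres space,
    concatenate counts over the union of gene lists, build the artificial
    hexagonal array and assign every spot new array coordinates, flag
    overlap exclusions, and produce the lowres image bundle (composing a
    canvas from the member hires images when no stitched composite is
    supplied).
    """
    ids = [a.area_id for a in areas]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate capture area ids: {ids}")
    coords = transform_group_coords(areas, plan, in_tissue_only=in_tissue_only)

    parts = []
    for area in areas:
        spots = (area.in_tissue_spots() if in_tissue_only else area.spots).copy()
        sub = coords[coords["area_id"] == area.area_id]
        spots["pxl_row_in_fullres"] = sub["pxl_row_stitched"].to_numpy()
        spots["pxl_col_in_fullres"] = sub["pxl_col_stitched"].to_numpy()
        spots["capture_area"] = area.area_id
        spots["orig_barcode"] = spots["barcode"]
        spots["barcode"] = spots["barcode"] + "_" + area.area_id
        parts.append(spots)
    table = pd.concat(parts, ignore_index=True)

    ref_sf = areas[[a.area_id for a in areas].index(plan.rescale.reference_area)].scalefactors
    xy = table[["pxl_col_in_fullres", "pxl_row_in_fullres"]].to_numpy()
    lattice = hexarray.build_hex_lattice(
        xy, ref_sf.spot_diameter_fullres, spot_diameter_um=spot_diameter_um
    )
    assignment = hexarray.assign_array_coords(xy, lattice)
    table["array_row"] = assignment["array_row"].to_numpy()
    table["array_col"] = assignment["array_col"].to_numpy()
    table["distance_to_centroid"] = assignment["distance_to_centroid"].to_numpy()

    have_counts = all(a.counts is not None for a in areas)
    counts = _concat_counts(areas, table[["capture_area", "orig_barcode", "barcode"]]) \
        if have_counts else None
    table["sum_umi"] = counts.sum_umi().astype(int) if counts is not None else 0
    table = table.drop(columns=["orig_barcode"])

    table["exclude_overlapping"] = flag_exclude_overlapping(
        table, distance_overlap=distance_overlap, pitch_px=lattice.pitch_px
    )

    lowres = None
    sf = ref_sf
    if stitched_img is None and all(a.hires_image is not None for a in areas):
        stitched_img = compose_canvas(areas, plan)
    if stitched_img is not None:
        lowres, sf = make_lowres_bundle(stitched_img, plan, ref_sf, target_longest)

    return StitchedSample(
        group_id=plan.group_id,
        spots=table,
        counts=counts,
        scalefactors=sf,
        lowres_image=lowres,
        lattice=lattice,
    )


def merge_overlapping(sample: StitchedSample) -> StitchedSample:
    """Collapse each occupied array position to one spot, summing counts.

    The merged spot sits at the lattice centroid of its position, its
    ``in_tissue`` is 1 if any contributor's is, and a ``merged_from``
    provenance series lists the contributing barcodes.  The grand total of
    counts is conserved exactly.
    """
    spots = sample.spots
    groups = spots.groupby(["array_row", "array_col"], sort=True)
    rows = []
    provenance = []
    col_blocks = []
    counts = sample.counts
    csc = counts.counts.tocsc() if counts is not None else None
    for (r, c), idx in groups.groups.items():
        sub = spots.loc[idx]
        if sample.lattice is not None:
            cx, cy = sample.lattice.point(int(r), int(c))
        else:
            cx = sub["pxl_col_in_fullres"].mean()
            cy = sub["pxl_row_in_fullres"].mean()
        barcode = sub["barcode"].iloc[0] if len(sub) == 1 else f"merged_{r}_{c}_{sample.group_id}"
        rows.append(
            {
                "barcode": barcode,
                "in_tissue": int(sub["in_tissue"].max()),
                "array_row": int(r),
                "array_col": int(c),
                "pxl_row_in_fullres": float(cy),
                "pxl_col_in_fullres": float(cx),
                "capture_area": ",".join(sorted(sub["capture_area"].unique())),
                "exclude_overlapping": False,
                "distance_to_centroid": 0.0,
            }
        )
        provenance.append(";".join(sub["barcode"]))
        if csc is not None:
            positions = [counts.barcodes.index(b) for b in sub["barcode"]]
            col_blocks.append(np.asarray(csc[:, positions].sum(axis=1)).ravel())
    merged_spots = pd.DataFrame(rows)
    merged_counts = None
    if csc is not None:
        dense = np.column_stack(col_blocks) if col_blocks else np.zeros((len(counts.genes), 0))
        merged_counts = CountMatrix(
            genes=list(counts.genes),
            barcodes=merged_spots["barcode"].tolist(),
            counts=sp.csr_matrix(dense.astype(np.int64)),
        )
        merged_spots["sum_umi"] = merged_counts.sum_umi().astype(int)
    else:
        merged_spots["sum_umi"] = 0
    return StitchedSample(
        group_id=sample.group_id,
        spots=merged_spots,
        counts=merged_counts,
        scalefactors=sample.scalefactors,
        lowres_image=sample.lowres_image,
        lattice=sample.lattice,
        merged_from=pd.Series(provenance, index=merged_spots.index, name="merged_from"),
    )


def overlap_label_agreement(
    sample: StitchedSample, labels: Mapping[str, object]
) -> float | None:
    """Fraction of cross-area spot pairs at shared positions with equal labels.

    Over all unordered pairs of spots from different capture areas assigned
    the same array position, returns the proportion whose cluster labels
    agree; a position contested by three areas contributes three pairs.
    Returns ``None`` when the sample has no such pairs.

    Raises
    ------
    KeyError
        If a paired spot has no label.
    """
    pairs = sample.overlap_pairs()
    if pairs.empty:
        return None
    agree = 0
    for i, j in zip(pairs["index_a"], pairs["index_b"]):
        bi = sample.spots.at[i, "barcode"]
        bj = sample.spots.at[j, "barcode"]
        if bi not in labels:
            raise KeyError(f"no cluster label for overlapping spot {bi}")
        if bj not in labels:
            raise KeyError(f"no cluster label for overlapping spot {bj}")
        agree += labels[bi] == labels[bj]
    return agree / len(pairs)


def load_stitched_sample(directory, group_id: str | None = None) -> StitchedSample:
    """Read back a stitched group directory written by
    :func:`~spotstitch.spaceranger_io.write_group_spatial_dir`.

    The lattice is rebuilt from the stored coordinates and spot diameter so
    merge and agreement operations can run on a reloaded sample.
    """
    from pathlib import Path

    import imageio.v3 as iio

    from . import spaceranger_io as sio

    directory = Path(directory)
    spatial = directory / "spatial" if (directory / "spatial").is_dir() else directory
    spots = sio.read_tissue_positions(spatial / "tissue_positions.csv")
    if "capture_area" not in spots.columns:
        raise ValueError(f"{spatial}: not a stitched bundle (no capture_area column)")
    if "exclude_overlapping" in spots.columns:
        spots["exclude_overlapping"] = spots["exclude_overlapping"].astype(str).isin(
            ["True", "true", "1"]
        )
    sf = sio.read_scalefactors(spatial / "scalefactors_json.json")
    lowres_path = spatial / "tissue_lowres_image.png"
    lowres = np.asarray(iio.imread(lowres_path)) if lowres_path.exists() else None
    counts = None
    cdir = directory / "filtered_feature_bc_matrix"
    if (cdir / "matrix.mtx").exists() or (cdir / "matrix.mtx.gz").exists():
        counts = sio.read_count_matrix(cdir)
        order = {b: i for i, b in enumerate(counts.barcodes)}
        spots = spots.sort_values("barcode", key=lambda s: s.map(order)).reset_index(
            drop=True
        )
    xy = spots[["pxl_col_in_fullres", "pxl_row_in_fullres"]].to_numpy()
    lattice = hexarray.build_hex_lattice(xy, sf.spot_diameter_fullres)
    spots["sum_umi"] = counts.sum_umi().astype(int) if counts is not None else 0
    return StitchedSample(
        group_id=group_id or directory.name,
        spots=spots,
        counts=counts,
        scalefactors=sf,
        lowres_image=lowres,
        lattice=lattice,
    )
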