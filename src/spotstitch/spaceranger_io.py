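"""Read and write SpaceRanger-style spatial output bundles.

A Visium capture area processed by SpaceRanger ships a small bundle of
spatial files next to the count matrix:

* ``tissue_positions.csv`` — one row per barcoded spot with its hexagonal
  array indices and full-resolution pixel coordinates.  Two dialects exist
  in the wild: a headered CSV (current SpaceRanger) and the legacy
  headerless ``tissue_positions_list.csv`` with the same column order.
* ``scalefactors_json.json`` — flat JSON mapping the full-resolution pixel
  space onto the derivative hires/lowres images.
* ``tissue_hires_image.png`` — a downscaled microscopy image, at most
  2,000 pixels in its longest dimension.
* a MatrixMarket count matrix with barcode and feature id lists.

This module parses all of these into plain containers (pandas / scipy /
numpy) and writes the stitched group-level bundle back out in the same
formats so downstream tools see something shaped like SpaceRanger output.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ScaleFactors",
    "CountMatrix",
    "CaptureArea",
    "POSITION_COLUMNS",
    "read_scalefactors",
    "write_scalefactors",
    "read_tissue_positions",
    "write_tissue_positions",
    "read_count_matrix",
    "write_count_matrix",
    "read_capture_area",
    "write_group_spatial_dir",
]

#: canonical column order of tissue_positions.csv
POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


@dataclass
class ScaleFactors:
    """Scale factors relating fullres pixel coordinates to derivative images.

    Parameters
    ----------
    spot_diameter_fullres
        Diameter of one 55 µm Visium spot, in fullres pixels (``d``).
    tissue_hires_scalef
        Hires pixels per fullres pixel (``h``).
    tissue_lowres_scalef
        Lowres pixels per fullres pixel; optional.
    fiducial_diameter_fullres
        Fiducial marker diameter in fullres pixels; optional.
    extra
        Unrecognized keys, preserved verbatim for round-trip writing.
    """

    spot_diameter_fullres: float
    tissue_hires_scalef: float
    tissue_lowres_scalef: float | None = None
    fiducial_diameter_fullres: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "spot_diameter_fullres",
            "tissue_hires_scalef",
            "tissue_lowres_scalef",
            "fiducial_diameter_fullres",
        ):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if (
            self.tissue_lowres_scalef is not None
            and self.tissue_lowres_scalef > self.tissue_hires_scalef
        ):
            # expected for SpaceRanger output; a small stitched composite
            # upscaled to the lowres target can legitimately invert it
            warnings.warn(
                "tissue_lowres_scalef exceeds tissue_hires_scalef: "
                f"{self.tissue_lowres_scalef} > {self.tissue_hires_scalef}",
                stacklevel=2,
            )

    def to_dict(self) -> dict:
        out = dict(self.extra)
        out["spot_diameter_fullres"] = self.spot_diameter_fullres
        out["tissue_hires_scalef"] = self.tissue_hires_scalef
        if self.tissue_lowres_scalef is not None:
            out["tissue_lowres_scalef"] = self.tissue_lowres_scalef
        if self.fiducial_diameter_fullres is not None:
            out["fiducial_diameter_fullres"] = self.fiducial_diameter_fullres
        return out


def read_scalefactors(path: str | Path) -> ScaleFactors:
    """Parse ``scalefactors_json.json``.

    Raises
    ------
    KeyError
        If ``spot_diameter_fullres`` or ``tissue_hires_scalef`` is missing.
    """
    with open(path) as fh:
        raw = json.load(fh)
    for required in ("spot_diameter_fullres", "tissue_hires_scalef"):
        if required not in raw:
            raise KeyError(f"{required} missing from {path}")
    known = {
        "spot_diameter_fullres",
        "tissue_hires_scalef",
        "tissue_lowres_scalef",
        "fiducial_diameter_fullres",
    }
    return ScaleFactors(
        spot_diameter_fullres=float(raw["spot_diameter_fullres"]),
        tissue_hires_scalef=float(raw["tissue_hires_scalef"]),
        tissue_lowres_scalef=(
            float(raw["tissue_lowres_scalef"]) if "tissue_lowres_scalef" in raw else None
        ),
        fiducial_diameter_fullres=(
            float(raw["fiducial_diameter_fullres"])
            if "fiducial_diameter_fullres" in raw
            else None
        ),
        extra={k: v for k, v in raw.items() if k not in known},
    )


def write_scalefactors(sf: ScaleFactors, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(sf.to_dict(), fh, indent=2)
        fh.write("\n")
    return path


def read_tissue_positions(path: str | Path) -> pd.DataFrame:
    """Read spot positions from either tissue_positions dialect.

    The headered dialect is detected by the literal token ``barcode`` in the
    first line; otherwise the legacy headerless six-column order is assumed.
    Extra trailing columns (e.g. ``capture_area`` in stitched output) are
    kept.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.strip() == "":
        return pd.DataFrame(columns=POSITION_COLUMNS)
    headered = "barcode" in first
    if headered:
        df = pd.read_csv(path, dtype={"barcode": str})
        missing = [c for c in POSITION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing position columns {missing}")
    else:
        ncol = len(first.rstrip("\n").split(","))
        if ncol < 6:
            raise ValueError(
                f"{path}: headerless positions need >= 6 columns, row 1 has {ncol}"
            )
        df = pd.read_csv(path, header=None, dtype={0: str})
        df.columns = POSITION_COLUMNS + [f"extra_{i}" for i in range(df.shape[1] - 6)]
    for col in ("pxl_row_in_fullres", "pxl_col_in_fullres"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValueError(f"{path}: non-numeric {col} at data row {row}")
        df[col] = coerced.astype(float)
    for col in ("in_tissue", "array_row", "array_col"):
        df[col] = df[col].astype(int)
    # normalize column order, keep any extras at the end
    extras = [c for c in df.columns if c not in POSITION_COLUMNS]
    return df[POSITION_COLUMNS + extras].reset_index(drop=True)


def write_tissue_positions(df: pd.DataFrame, path: str | Path) -> Path:
    """Write positions in the headered dialect, 6-decimal pixel coordinates."""
    path = Path(path)
    out = df.copy()
    for col in ("pxl_row_in_fullres", "pxl_col_in_fullres"):
        out[col] = out[col].map(lambda v: f"{v:.6f}")
    out.to_csv(path, index=False)
    return path


@dataclass
class CountMatrix:
    """A genes × spots integer count matrix with its id lists."""

    genes: list[str]
    barcodes: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sum_umi(self) -> np.ndarray:
        """Total UMIs per spot."""
        return np.asarray(self.counts.sum(axis=0)).ravel()


def _read_id_list(directory: Path, names: Iterable[str]) -> tuple[list[str], str] | None:
    for name in names:
        for candidate in (directory / name, directory / (name + ".gz")):
            if candidate.exists():
                opener = gzip.open if candidate.suffix == ".gz" else open
                with opener(candidate, "rt") as fh:
                    ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
                return ids, candidate.name
    return None


def read_count_matrix(directory: str | Path) -> CountMatrix:
    """Read a MatrixMarket count bundle (matrix.mtx + barcodes + features).

    Accepts optionally gzip-compressed files and the older ``genes.tsv``
    feature-file name.  Barcode order is preserved from file.
    """
    directory = Path(directory)
    mtx = None
    for name in ("matrix.mtx", "matrix.mtx.gz"):
        if (directory / name).exists():
            mtx = directory / name
            break
    if mtx is None:
        raise FileNotFoundError(f"no matrix.mtx[.gz] in {directory}")
    counts = sp.csr_matrix(scipy.io.mmread(mtx))
    got = _read_id_list(directory, ["barcodes.tsv", "barcodes.txt"])
    if got is None:
        raise FileNotFoundError(f"no barcodes file in {directory}")
    barcodes, _ = got
    got = _read_id_list(directory, ["features.tsv", "genes.tsv", "features.txt"])
    if got is None:
        raise FileNotFoundError(f"no features file in {directory}")
    genes, _ = got
    if counts.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"{mtx}: header declares {counts.shape}, id lists give "
            f"({len(genes)}, {len(barcodes)})"
        )
    return CountMatrix(genes=genes, barcodes=barcodes, counts=counts)


def write_count_matrix(cm: CountMatrix, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(directory / "matrix.mtx", sp.coo_matrix(cm.counts))
    (directory / "barcodes.tsv").write_text("\n".join(cm.barcodes) + "\n")
    (directory / "features.tsv").write_text("\n".join(cm.genes) + "\n")
    return directory


@dataclass
class CaptureArea:
    """One Visium capture area: spots, scale factors, hires image, counts."""

    area_id: str
    spots: pd.DataFrame
    scalefactors: ScaleFactors
    hires_image: np.ndarray | None = None
    counts: CountMatrix | None = None

    def __post_init__(self) -> None:
        if self.spots["barcode"].duplicated().any():
            dup = self.spots["barcode"][self.spots["barcode"].duplicated()].iloc[0]
            raise ValueError(f"{self.area_id}: duplicate barcode {dup}")
        if self.hires_image is not None and max(self.hires_image.shape[:2]) > 2000:
            raise ValueError(
                f"{self.area_id}: hires image longest dimension "
                f"{max(self.hires_image.shape[:2])} exceeds 2000 px"
            )

    def in_tissue_spots(self) -> pd.DataFrame:
        return self.spots[self.spots["in_tissue"] == 1].reset_index(drop=True)


def read_capture_area(directory: str | Path, area_id: str | None = None) -> CaptureArea:
    """Read a whole SpaceRanger-style capture-area directory.

    Expects ``spatial/`` with positions, scale factors and hires image, and
    a count-matrix directory (``filtered_feature_bc_matrix/`` or the files
    directly under ``counts/``).
    """
    directory = Path(directory)
    if area_id is None:
        area_id = directory.name
    spatial = directory / "spatial" if (directory / "spatial").is_dir() else directory
    pos_path = None
    for name in ("tissue_positions.csv", "tissue_positions_list.csv"):
        if (spatial / name).exists():
            pos_path = spatial / name
            break
    if pos_path is None:
        raise FileNotFoundError(f"no tissue positions file in {spatial}")
    spots = read_tissue_positions(pos_path)
    sf = read_scalefactors(spatial / "scalefactors_json.json")
    img_path = spatial / "tissue_hires_image.png"
    hires = np.asarray(iio.imread(img_path)) if img_path.exists() else None
    counts = None
    for sub in ("filtered_feature_bc_matrix", "counts", "."):
        cdir = directory / sub
        if (cdir / "matrix.mtx").exists() or (cdir / "matrix.mtx.gz").exists():
            counts = read_count_matrix(cdir)
            break
    return CaptureArea(
        area_id=area_id, spots=spots, scalefactors=sf, hires_image=hires, counts=counts
    )


def write_group_spatial_dir(sample, out: str | Path) -> Path:
    """Write the group-level SpaceRanger-imitating spatial directory.

    Produces ``tissue_positions.csv`` (headered, with ``capture_area`` and
    ``exclude_overlapping`` columns), ``tissue_lowres_image.png`` and
    ``scalefactors_json.json``, plus the combined count bundle under
    ``filtered_feature_bc_matrix/``.

    Parameters
    ----------
    sample
        A :class:`~spotstitch.stitcher.StitchedSample`.
    out
        Output directory (created if needed).
    """
    out = Path(out)
    spatial = out / "spatial"
    spatial.mkdir(parents=True, exist_ok=True)
    cols = POSITION_COLUMNS + ["capture_area", "exclude_overlapping"]
    write_tissue_positions(sample.spots[cols], spatial / "tissue_positions.csv")
    write_scalefactors(sample.scalefactors, spatial / "scalefactors_json.json")
    if sample.lowres_image is not None:
        iio.imwrite(spatial / "tissue_lowres_image.png", sample.lowres_image)
    if sample.counts is not None:
        write_count_matrix(sample.counts, out / "filtered_feature_bc_matrix")
    return out
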