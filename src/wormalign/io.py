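"""Domain types and file I/O for neuron point clouds, hull masks and atlases.

Point clouds and atlases travel as delimited text (CSV or TSV, chosen by file
extension) with a header row; hull masks are single-channel TIFF or PNG
rasters.  All in-memory coordinates are real-valued micrometres — pixel units
exist only inside :func:`read_hull_mask`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RAW = "raw"
CANONICAL = "canonical"

#: Canonical anterior-posterior extent of a straightened worm, in μm.
CANONICAL_EXTENT = (0.0, 800.0)


class ValidationError(ValueError):
    """Raised when a file or in-memory object violates a domain invariant."""


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


@dataclass
class NeuronPointCloud:
    """An ordered set of neuron somata in 3D.

    Parameters
    ----------
    positions : (n, 3) float array
        Soma centre coordinates in μm.
    names : sequence of str, optional
        Neuron identities (e.g. ``"AVAL"``); unique when present.
    colors : sequence of int, optional
        Discrete fluorophore-barcode color indices; present for every record
        or for none.
    frame : {"raw", "canonical"}
        Whether positions live in the imaging frame or the straightened
        canonical frame.
    """

    positions: np.ndarray
    names: list[str] | None = None
    colors: np.ndarray | None = None
    frame: str = RAW

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("positions must be finite")
        if self.names is not None:
            self.names = [str(n) for n in self.names]
            if len(self.names) != len(self.positions):
                raise ValidationError("names length does not match positions")
            dup = {n for n in self.names if self.names.count(n) > 1}
            if dup:
                raise ValidationError(f"duplicate neuron names: {sorted(dup)}")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=int).reshape(-1)
            if len(self.colors) != len(self.positions):
                raise ValidationError("colors length does not match positions")
            if np.any(self.colors < 0):
                raise ValidationError("color indices must be non-negative")
        if self.frame not in (RAW, CANONICAL):
            raise ValidationError(f"unknown frame {self.frame!r}")

    def __len__(self) -> int:
        return len(self.positions)

    def copy(self) -> "NeuronPointCloud":
        return NeuronPointCloud(
            self.positions.copy(),
            None if self.names is None else list(self.names),
            None if self.colors is None else self.colors.copy(),
            self.frame,
        )

    def subset(self, index: np.ndarray) -> "NeuronPointCloud":
        """Row-subset (order of `index` preserved)."""
        index = np.asarray(index)
        return NeuronPointCloud(
            self.positions[index],
            None if self.names is None else [self.names[i] for i in index],
            None if self.colors is None else self.colors[index],
            self.frame,
        )

    def with_positions(self, positions: np.ndarray, frame: str | None = None) -> "NeuronPointCloud":
        out = self.copy()
        out.positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        if frame is not None:
            out.frame = frame
        return out

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, object] = {}
        if self.names is not None:
            cols["name"] = self.names
        cols["x"], cols["y"], cols["z"] = self.positions.T
        if self.colors is not None:
            cols["color"] = self.colors
        return pd.DataFrame(cols)


@dataclass
class HullMask:
    """A binary 2D silhouette of the worm body at the largest-area z-slice."""

    grid: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValidationError("hull mask must be 2D")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be positive")

    def validate(self) -> None:
        from scipy import ndimage

        if not self.grid.any():
            raise ValidationError("hull mask has empty foreground")
        _, n = ndimage.label(self.grid)
        if n != 1:
            raise ValidationError(f"hull mask has {n} connected components, expected 1")
        border = np.concatenate(
            [self.grid[0], self.grid[-1], self.grid[:, 0], self.grid[:, -1]]
        )
        if border.any():
            raise ValidationError(
                "hull foreground touches the raster border; pad the image first"
            )


@dataclass
class Atlas:
    """Named canonical neuron positions with per-axis positional spread.

    ``positions`` are componentwise medians over contributing worms;
    ``spreads`` are per-axis median absolute deviations (both μm).
    """

    names: list[str]
    positions: np.ndarray
    spreads: np.ndarray | None = None
    colors: np.ndarray | None = None
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.names = [str(n) for n in self.names]
        if len(self.names) != len(self.positions):
            raise ValidationError("atlas names/positions length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("atlas names must be unique")
        if self.spreads is not None:
            self.spreads = np.asarray(self.spreads, dtype=float).reshape(-1, 3)
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=int).reshape(-1)
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=int).reshape(-1)

    def __len__(self) -> int:
        return len(self.names)

    @property
    def extent(self) -> tuple[float, float]:
        return float(self.positions[:, 0].min()), float(self.positions[:, 0].max())

    def as_pointcloud(self) -> NeuronPointCloud:
        return NeuronPointCloud(
            self.positions.copy(), list(self.names),
            None if self.colors is None else self.colors.copy(),
            frame=CANONICAL,
        )

    def index_of(self, name: str) -> int:
        return self.names.index(name)


DEFAULT_DIALECT: Mapping[str, str] = {
    "name": "name", "x": "x", "y": "y", "z": "z", "color": "color",
}


def read_pointcloud(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    frame: str = RAW,
) -> NeuronPointCloud:
    """Read a neuron point cloud from a delimited text table.

    The ``dialect`` maps the standard fields ``name, x, y, z, color`` to the
    file's column headers; ``name`` and ``color`` are optional columns, the
    coordinates are required.  Missing values use the empty field.
    """
    path = Path(path)
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    for axis in "xyz":
        col = d[axis]
        if col not in df.columns:
            raise ValidationError(f"{path}: required column {col!r} missing")
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            rows = list(df.index[bad][:5])
            raise ValidationError(f"{path}: non-numeric {col!r} at rows {rows}")
        if df[col].isna().any():
            rows = list(df.index[df[col].isna()][:5])
            raise ValidationError(f"{path}: missing coordinate {col!r} at rows {rows}")
    positions = df[[d["x"], d["y"], d["z"]]].to_numpy(dtype=float)
    names = None
    if d["name"] in df.columns:
        col = df[d["name"]]
        if col.isna().any():
            rows = list(df.index[col.isna()][:5])
            raise ValidationError(f"{path}: missing name at rows {rows}")
        names = [str(v) for v in col]
        dup = col[col.duplicated()].tolist()
        if dup:
            raise ValidationError(f"{path}: duplicate names {dup[:5]}")
    colors = None
    if d["color"] in df.columns and df[d["color"]].notna().any():
        col = df[d["color"]]
        if col.isna().any():
            rows = list(df.index[col.isna()][:5])
            raise ValidationError(
                f"{path}: color defined for some rows but missing at rows {rows}"
            )
        colors = col.to_numpy(dtype=int)
    return NeuronPointCloud(positions, names, colors, frame=frame)


def write_pointcloud(cloud: NeuronPointCloud, path: str | Path) -> None:
    """Write a cloud as delimited text, losslessly round-trippable."""
    path = Path(path)
    df = cloud.to_dataframe()
    if len(cloud) == 0 and cloud.names is None:
        # header-only file still records the coordinate columns
        df = pd.DataFrame(columns=["x", "y", "z"])
    # pandas' default float formatting is repr-based and round-trips exactly
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_hull_mask(path: str | Path, pixel_size: float) -> HullMask:
    """Load and binarize a worm-hull raster, keeping the largest blob.

    Non-boolean rasters are thresholded at half their maximum value.  Smaller
    disconnected blobs (debris, eggs) are discarded with a warning; an empty
    foreground or one touching the image border is an error.
    """
    from scipy import ndimage

    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        img = np.asarray(tifffile.imread(path))
    else:
        import imageio.v3 as iio

        img = np.asarray(iio.imread(path))
    if img.ndim == 3:  # collapse any channel axis
        img = img.max(axis=-1 if img.shape[-1] <= 4 else 0)
    if img.dtype == bool:
        grid = img
    else:
        mx = img.max()
        if mx == 0:
            raise ValidationError(f"{path}: all-background image")
        grid = img > mx / 2
    if not grid.any():
        raise ValidationError(f"{path}: empty foreground after thresholding")
    labels, n = ndimage.label(grid)
    if n > 1:
        sizes = ndimage.sum_labels(grid, labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        logger.warning("%s: %d foreground blobs, keeping the largest", path, n)
        warnings.warn(f"{path}: {n} foreground blobs, keeping the largest")
        grid = labels == keep
    mask = HullMask(grid, pixel_size)
    mask.validate()
    return mask


def read_atlas(path: str | Path) -> Atlas:
    """Read an atlas table (``name,x,y,z[,sx,sy,sz][,color][,count]``)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    for col in ("name", "x", "y", "z"):
        if col not in df.columns:
            raise ValidationError(f"{path}: required atlas column {col!r} missing")
    spreads = None
    if {"sx", "sy", "sz"} <= set(df.columns):
        spreads = df[["sx", "sy", "sz"]].to_numpy(dtype=float)
    colors = None
    if "color" in df.columns and df["color"].notna().all():
        colors = df["color"].to_numpy(dtype=int)
    counts = None
    if "count" in df.columns:
        counts = df["count"].to_numpy(dtype=int)
    return Atlas(
        [str(n) for n in df["name"]],
        df[["x", "y", "z"]].to_numpy(dtype=float),
        spreads=spreads, colors=colors, counts=counts,
    )


def write_atlas(atlas: Atlas, path: str | Path) -> None:
    path = Path(path)
    cols: dict[str, object] = {"name": atlas.names}
    cols["x"], cols["y"], cols["z"] = atlas.positions.T
    if atlas.spreads is not None:
        cols["sx"], cols["sy"], cols["sz"] = atlas.spreads.T
    if atlas.colors is not None:
        cols["color"] = atlas.colors
    if atlas.counts is not None:
        cols["count"] = atlas.counts
    pd.DataFrame(cols).to_csv(path, sep=_sep_for(path), index=False)


def neuron_name_list(exclude_can: bool = True) -> list[str]:
    """The standard 302 adult-hermaphrodite neuron names.

    With ``exclude_can`` (default) the CANL/CANR pair — absent from
    panneuronal imaging strains — is dropped, yielding the 300 names an
    imaging-derived atlas can carry.
    """
    res = Path(__file__).parent / "data" / "neuron_names.txt"
    names = [ln.strip() for ln in res.read_text().splitlines() if ln.strip()]
    if exclude_can:
        names = [n for n in names if n not in ("CANL", "CANR")]
    return names
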