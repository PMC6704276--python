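"""MSI data model, readers/writers, TIC normalization, and annotation masks.

A mass spectrometry imaging (MSI) run produces one spectrum per pixel of a
regular grid (here nominally 70 μm pitch, m/z 350–1600).  The dataset is held
as a dense ``(n_pixels, n_channels)`` intensity matrix plus integer grid
coordinates.  Two on-disk dialects are supported: continuous-mode imzML (via
pyimzml) and a plain TSV matrix with an m/z sidecar line, which makes
human-diffable fixtures.

Tumor annotations drawn by a pathologist on the H&E image arrive as polygons;
they are mapped through the registration chain into the MSI frame and
rasterized with the even-odd rule at pixel centers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import AffineTransform2D

logger = logging.getLogger(__name__)


@dataclass
class MSIDataset:
    """Pixel grid coordinates, spectra, and the shared m/z axis.

    Parameters
    ----------
    coords:
        ``(n_pixels, 2)`` integer grid positions (x = column, y = row).
    spectra:
        ``(n_pixels, n_channels)`` non-negative intensities.
    mz_axis:
        Strictly increasing m/z value per channel.
    pitch:
        Physical pixel spacing in micrometers (default 70).
    """

    coords: np.ndarray
    spectra: np.ndarray
    mz_axis: np.ndarray
    pitch: float = 70.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        if self.spectra.shape != (len(self.coords), len(self.mz_axis)):
            raise ValueError("spectra must be (n_pixels, n_channels)")
        if len({tuple(c) for c in self.coords}) != len(self.coords):
            raise ValueError("duplicate pixel coordinates")
        if np.any(np.diff(self.mz_axis) <= 0):
            raise ValueError("mz_axis must be strictly increasing")
        if np.any(self.spectra < 0):
            raise ValueError("intensities must be non-negative")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    @property
    def n_channels(self) -> int:
        return len(self.mz_axis)

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(height, width) of the minimal raster containing all pixels."""
        return (int(self.coords[:, 1].max()) + 1, int(self.coords[:, 0].max()) + 1)

    def to_image(self, channel: int) -> np.ndarray:
        """Rasterize one channel onto the grid (NaN where no pixel exists)."""
        img = np.full(self.grid_shape, np.nan)
        img[self.coords[:, 1], self.coords[:, 0]] = self.spectra[:, channel]
        return img


@dataclass
class PixelMask:
    """A boolean raster in a named frame."""

    frame: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("mask must be a non-empty 2-D raster")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class AnnotationSet:
    """Pathologist polygons (vertex lists) in a named frame."""

    frame: str
    polygons: list

    def __post_init__(self) -> None:
        if not self.frame:
            raise ValueError("annotation frame must be named")
        self.polygons = [np.asarray(p, dtype=float) for p in self.polygons]
        for p in self.polygons:
            if p.ndim != 2 or p.shape[1] != 2 or len(p) < 3:
                raise ValueError("every polygon needs >= 3 (x, y) vertices")

    @classmethod
    def read_json(cls, path: str | Path) -> "AnnotationSet":
        d = json.loads(Path(path).read_text())
        return cls(frame=d["frame"], polygons=d["polygons"])

    def write_json(self, path: str | Path) -> None:
        d = {"frame": self.frame, "polygons": [p.tolist() for p in self.polygons]}
        Path(path).write_text(json.dumps(d) + "\n")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MZ_SIDECAR_PREFIX = "#mz:"


def write_matrix(ds: MSIDataset, path: str | Path) -> None:
    """Write the TSV matrix dialect: an ``#mz:`` sidecar line with the m/z
    axis, then a header ``x y channel_1..channel_n``, then one row per pixel."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_MZ_SIDECAR_PREFIX + "\t".join(repr(float(v)) for v in ds.mz_axis) + "\n")
        header = ["x", "y"] + [f"channel_{i + 1}" for i in range(ds.n_channels)]
        fh.write("\t".join(header) + "\n")
        for (x, y), row in zip(ds.coords, ds.spectra):
            fh.write(f"{x}\t{y}\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_matrix(path: str | Path, pitch: float = 70.0) -> MSIDataset:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith(_MZ_SIDECAR_PREFIX):
            raise ValueError(f"{path}:1: expected an '{_MZ_SIDECAR_PREFIX}' sidecar line")
        mz_axis = np.array([float(v) for v in first[len(_MZ_SIDECAR_PREFIX):].split()])
        header = fh.readline().split()
        if header[:2] != ["x", "y"]:
            raise ValueError(f"{path}:2: header must start with 'x\\ty'")
        coords, spectra = [], []
        for lineno, line in enumerate(fh, start=3):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 2 + len(mz_axis):
                raise ValueError(
                    f"{path}:{lineno}: expected {2 + len(mz_axis)} fields, got {len(fields)}"
                )
            coords.append((int(fields[0]), int(fields[1])))
            spectra.append([float(v) for v in fields[2:]])
    return MSIDataset(np.array(coords), np.array(spectra), mz_axis, pitch=pitch)


def write_imzml(ds: MSIDataset, path: str | Path) -> None:
    """Write continuous-mode imzML (an .imzML/.ibd pair) via pyimzml.

    Grid coordinates are converted to the 1-based convention of the format.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    with ImzMLWriter(str(path), mode="continuous") as writer:
        for (x, y), row in zip(ds.coords, ds.spectra):
            writer.addSpectrum(ds.mz_axis, row, (int(x) + 1, int(y) + 1, 1))


def read_imzml(path: str | Path, pitch: float = 70.0) -> MSIDataset:
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    coords, spectra = [], []
    mz_axis = None
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mzs, intensities = parser.getspectrum(i)
        if mz_axis is None:
            mz_axis = np.asarray(mzs, float)
        coords.append((int(x) - 1, int(y) - 1))
        spectra.append(np.asarray(intensities, float))
    if mz_axis is None:
        raise ValueError(f"{path}: no spectra found")
    return MSIDataset(np.array(coords), np.array(spectra), mz_axis, pitch=pitch)


def load_msi(path: str | Path, format: str | None = None, pitch: float = 70.0) -> MSIDataset:
    """Load a dataset from ``imzml`` or the ``matrix`` TSV dialect.

    The format is inferred from the file extension when not given.
    """
    path = Path(path)
    if format is None:
        format = "imzml" if path.suffix.lower() == ".imzml" else "matrix"
    if format == "imzml":
        return read_imzml(path, pitch=pitch)
    if format == "matrix":
        return read_matrix(path, pitch=pitch)
    raise ValueError(f"unknown MSI format: {format!r}")


# ---------------------------------------------------------------------------
# Processing
# ---------------------------------------------------------------------------


def tic_normalize(ds: MSIDataset) -> MSIDataset:
    """Normalize every spectrum to its total ion current (unit sum).

    Pixels whose spectrum sums to zero carry no signal; they are dropped and
    the count is logged.  Raises if the whole dataset is empty of signal.
    """
    tic = ds.spectra.sum(axis=1)
    keep = tic > 0
    if not keep.any():
        raise ValueError("all spectra have zero total ion current")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("tic_normalize: dropped %d zero-TIC pixel(s)", n_dropped)
    return MSIDataset(
        ds.coords[keep],
        ds.spectra[keep] / tic[keep, None],
        ds.mz_axis,
        pitch=ds.pitch,
    )


def points_in_polygon(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Even-odd (ray-crossing) point-in-polygon test, vectorized over points."""
    pts = np.asarray(points, float)
    poly = np.asarray(polygon, float)
    px, py = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        crosses = (y1 > py) != (y2 > py)
        if not crosses.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < x_int)
    return inside


def rasterize_annotations(
    ann: AnnotationSet,
    chain: AffineTransform2D,
    grid: MSIDataset,
) -> PixelMask:
    """Rasterize annotation polygons onto the MSI grid.

    ``chain`` maps the annotation frame into the MSI frame.  A grid pixel is
    inside the mask iff its center passes the even-odd rule for at least one
    transformed polygon.
    """
    height, width = grid.grid_shape
    yy, xx = np.mgrid[0:height, 0:width]
    centers = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    mask = np.zeros(height * width, dtype=bool)
    for poly in ann.polygons:
        mask |= points_in_polygon(centers, chain.apply(poly))
    return PixelMask(frame="msi", values=mask.reshape(height, width))


def mask_dataset(ds: MSIDataset, mask: PixelMask) -> MSIDataset:
    """Restrict a dataset to the pixels where ``mask`` is true."""
    height, width = mask.shape
    keep = np.array(
        [
            0 <= y < height and 0 <= x < width and mask.values[y, x]
            for x, y in ds.coords
        ]
    )
    if not keep.any():
        raise ValueError("mask removes every pixel")
    return MSIDataset(ds.coords[keep], ds.spectra[keep], ds.mz_axis, pitch=ds.pitch)
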