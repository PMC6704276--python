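"""Morphological cleanup of the segmentation image and ROI boundary tracing.

The segment label image is post-processed to make the regions practical to
microdissect: a 2×2 grayscale opening smooths the label raster, each segment
is split into a binary mask, impurities of ≤ 30 pixels (4-connected) are
removed, holes (8-connected background) are filled, the mask is warped to
the histology frame by nearest-pixel inverse mapping, and the external
boundary of every 8-connected region is traced with the Moore-neighbor
algorithm, yielding one closed pixel-coordinate polygon per region.

Connectivity follows the classic raster-morphology mix: 4-connected
foreground for area filtering, 8-connected background for hole filling, and
8-connected foreground for boundary tracing.  Nearest-neighbor rounding is
``floor(v + 0.5)`` per axis (0.5 rounds up); boundary vertices and warped
masks are bit-exact under these rules.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .geometry import AffineTransform2D

logger = logging.getLogger(__name__)

#: Default area (pixels, 4-connected) at or below which a component is removed.
DEFAULT_MAX_REMOVED_AREA = 30

_MOORE_OFFSETS = [  # clockwise from West, (dy, dx), y pointing down
    (0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1),
]


@dataclass
class LabelImage:
    """Integer segment raster: 0 = unassigned, 1..k = segment id."""

    frame: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("label image must be 2-D")
        if self.values.min() < 0:
            raise ValueError("labels must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_dataset_labels(cls, coords: np.ndarray, labels: np.ndarray,
                            shape: tuple[int, int] | None = None,
                            frame: str = "msi") -> "LabelImage":
        """Scatter per-pixel labels onto the raster (0 where no pixel)."""
        coords = np.asarray(coords, int)
        if shape is None:
            shape = (coords[:, 1].max() + 1, coords[:, 0].max() + 1)
        img = np.zeros(shape, dtype=int)
        img[coords[:, 1], coords[:, 0]] = labels
        return cls(frame=frame, values=img)

    def write_tsv(self, path: str | Path) -> None:
        np.savetxt(path, self.values, fmt="%d", delimiter="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, frame: str = "msi") -> "LabelImage":
        return cls(frame=frame, values=np.loadtxt(path, dtype=int, delimiter="\t", ndmin=2))


@dataclass
class RoiBoundarySet:
    """Closed external-boundary polygons of one segment's regions.

    Each polygon is a list of ``(x, y)`` pixel coordinates in traversal
    order with the first vertex repeated as the last (closed); polygons
    belong to distinct 8-connected components.
    """

    frame: str
    segment_id: int
    polygons: list

    def __post_init__(self) -> None:
        for poly in self.polygons:
            if len(poly) < 2 or tuple(poly[0]) != tuple(poly[-1]):
                raise ValueError("every boundary polygon must be closed")

    def write_json(self, path: str | Path) -> None:
        d = {
            "frame": self.frame,
            "segment_id": self.segment_id,
            "polygons": [[list(map(float, v)) for v in p] for p in self.polygons],
        }
        Path(path).write_text(json.dumps(d) + "\n")

    @classmethod
    def read_json(cls, path: str | Path) -> "RoiBoundarySet":
        d = json.loads(Path(path).read_text())
        return cls(d["frame"], d["segment_id"],
                   [[tuple(v) for v in p] for p in d["polygons"]])


# ---------------------------------------------------------------------------
# Morphology
# ---------------------------------------------------------------------------


def smooth_labels(img: LabelImage) -> LabelImage:
    """Grayscale morphological opening with a 2×2 square, top-left anchored.

    Erosion takes the window minimum over ``{(y..y+1), (x..x+1)}`` (padded
    with +inf outside the raster); the subsequent dilation uses the
    reflected element, so the opening is anti-extensive and idempotent on
    the integer label raster.
    """
    v = img.values.astype(float)
    pinf = np.pad(v, ((0, 1), (0, 1)), constant_values=np.inf)
    eroded = np.minimum.reduce(
        [pinf[dy:dy + v.shape[0], dx:dx + v.shape[1]] for dy in (0, 1) for dx in (0, 1)]
    )
    ninf = np.pad(eroded, ((1, 0), (1, 0)), constant_values=-np.inf)
    opened = np.maximum.reduce(
        [ninf[dy:dy + v.shape[0], dx:dx + v.shape[1]] for dy in (0, 1) for dx in (0, 1)]
    )
    return LabelImage(frame=img.frame, values=opened.astype(int))


def split_segments(img: LabelImage, k: int) -> list[np.ndarray]:
    """Binary mask per segment id 1..k (pairwise disjoint, union = labeled area)."""
    if img.values.max() > k:
        raise ValueError(f"label image contains ids above k={k}")
    return [img.values == s for s in range(1, k + 1)]


def remove_small_regions(mask: np.ndarray,
                         max_removed_area: int = DEFAULT_MAX_REMOVED_AREA) -> np.ndarray:
    """Delete 4-connected components of area ≤ ``max_removed_area`` pixels."""
    mask = np.asarray(mask, bool)
    return morphology.remove_small_objects(
        mask, max_size=max_removed_area, connectivity=1
    )


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill holes: background components (8-connected) not reachable from the
    image border become foreground."""
    mask = np.asarray(mask, bool)
    bg_labels, _ = ndimage.label(~mask, structure=np.ones((3, 3), int))
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    reachable = np.unique(bg_labels[border & ~mask])
    hole = ~mask & ~np.isin(bg_labels, reachable)
    return mask | hole


def upscale_mask(mask: np.ndarray, t: AffineTransform2D,
                 target_shape: tuple[int, int]) -> np.ndarray:
    """Warp a binary mask into a target raster by nearest-pixel inverse mapping.

    ``t`` maps mask (source) coordinates into the target frame.  Each target
    pixel center is pulled back through ``t⁻¹`` and rounded with
    ``floor(v + 0.5)``; pixels mapping outside the source raster are false.
    """
    mask = np.asarray(mask, bool)
    height, width = target_shape
    yy, xx = np.mgrid[0:height, 0:width]
    src = t.inverse().apply(np.column_stack([xx.ravel(), yy.ravel()]).astype(float))
    sx = np.floor(src[:, 0] + 0.5).astype(int)
    sy = np.floor(src[:, 1] + 0.5).astype(int)
    valid = (0 <= sx) & (sx < mask.shape[1]) & (0 <= sy) & (sy < mask.shape[0])
    out = np.zeros(height * width, dtype=bool)
    out[valid] = mask[sy[valid], sx[valid]]
    return out.reshape(height, width)


# ---------------------------------------------------------------------------
# Boundary tracing
# ---------------------------------------------------------------------------


def _trace_one(padded: np.ndarray, start: tuple[int, int]) -> list[tuple[int, int]]:
    """Moore-neighbor trace (clockwise, Jacob's stopping criterion) of the
    component containing ``start`` in a zero-padded boolean raster.

    ``start`` must be the component's first foreground pixel in raster order,
    so its West neighbor is background.  Returns (y, x) pixels in padded
    coordinates, without the closing repeat.
    """
    if not any(padded[start[0] + dy, start[1] + dx] for dy, dx in _MOORE_OFFSETS):
        return [start]  # isolated pixel
    path = [start]
    current, backtrack = start, (start[0], start[1] - 1)
    first_move: tuple[int, int] | None = None
    for _ in range(16 * int(padded.sum()) + 16):
        i = _MOORE_OFFSETS.index((backtrack[0] - current[0], backtrack[1] - current[1]))
        nxt = None
        for j in range(1, 9):
            dy, dx = _MOORE_OFFSETS[(i + j) % 8]
            cand = (current[0] + dy, current[1] + dx)
            if padded[cand]:
                nxt = cand
                break
            backtrack = cand
        assert nxt is not None
        # stop when the walk is about to repeat its first move from the start
        if first_move is None:
            first_move = nxt
        elif current == start and nxt == first_move:
            return path
        path.append(nxt)
        current = nxt
    raise RuntimeError("boundary trace failed to terminate")  # pragma: no cover


def trace_boundaries(mask: np.ndarray, segment_id: int = 1,
                     frame: str = "he") -> RoiBoundarySet:
    """External boundary of every 8-connected region as a closed polygon.

    One polygon per component; holes are ignored.  Vertices are ``(x, y)``
    coordinates of the boundary pixels in Moore-trace order, with the first
    vertex repeated last to close the loop.  A single-pixel region yields
    the degenerate polygon ``[(x, y), (x, y)]``.
    """
    mask = np.asarray(mask, bool)
    labeled = measure.label(mask, connectivity=2)
    polygons = []
    for comp_id in range(1, labeled.max() + 1):
        comp = labeled == comp_id
        padded = np.pad(comp, 1)
        ys, xs = np.nonzero(padded)
        start = (int(ys[0]), int(xs[0]))  # raster-order first pixel
        pix = _trace_one(padded, start)
        poly = [(int(x) - 1, int(y) - 1) for y, x in pix]
        if len(poly) == 1 or poly[-1] != poly[0]:
            poly.append(poly[0])
        polygons.append(poly)
    return RoiBoundarySet(frame=frame, segment_id=segment_id, polygons=polygons)


def process_segment_masks(
    labels: LabelImage,
    k: int,
    msi_to_target: AffineTransform2D,
    target_shape: tuple[int, int],
    max_removed_area: int = DEFAULT_MAX_REMOVED_AREA,
    target_frame: str = "he",
) -> list[RoiBoundarySet]:
    """The full post-processing chain for every segment.

    Order: smooth → split → remove-small → fill-holes → upscale → trace.
    Segments whose mask empties out are returned with zero polygons.
    """
    smoothed = smooth_labels(labels)
    boundary_sets = []
    for s, mask in enumerate(split_segments(smoothed, k), start=1):
        mask = remove_small_regions(mask, max_removed_area)
        mask = fill_holes(mask)
        warped = upscale_mask(mask, msi_to_target, target_shape)
        boundary_sets.append(trace_boundaries(warped, segment_id=s, frame=target_frame))
    return boundary_sets


# ---------------------------------------------------------------------------
# Mask I/O
# ---------------------------------------------------------------------------


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    from PIL import Image

    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(str(path))


def read_mask_png(path: str | Path) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(str(path))) > 0
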