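"""Coordinate frames, landmark affine registration, and error propagation.

The tool chains several planar coordinate systems: the MSI pixel grid, the
high-resolution optical image of the matrix-covered section, the H&E image of
the same section after staining, and the stage coordinates of the laser
microdissection (LMD) instrument.  Each hop between frames is estimated from
a handful of manually picked landmark pairs (laser-shot marks, Tipp-Ex
fiducial spots) as a 2-D affine transform, and per-hop registration errors
are summarized and propagated additively to bound the end-to-end error.

Conventions: 0-based pixel indices, ``x`` is the column, ``y`` the row, ``y``
increases downward, and a point refers to the pixel center.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MICROMETERS_PER_INCH = 25400.0

#: Triangle-area tolerance (pixel^2) below which control points are degenerate.
COLLINEARITY_TOL = 1e-9


class InsufficientPointsError(ValueError):
    """Fewer control-point pairs than an affine fit requires (minimum 3)."""


class DegenerateGeometryError(ValueError):
    """Source landmarks are (numerically) collinear; the fit is not invertible."""


class FrameChainError(ValueError):
    """Transforms were composed across mismatched coordinate frames."""


@dataclass(frozen=True)
class Frame:
    """A named planar coordinate frame, optionally with a physical pixel size.

    Parameters
    ----------
    name:
        Identifier, e.g. ``"msi"``, ``"optical"``, ``"he"``, ``"lmd"``.
    pixel_size:
        Physical extent of one pixel as ``(x, y)`` in micrometers, if known.
    """

    name: str
    pixel_size: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("frame name must be non-empty")
        if self.pixel_size is not None:
            if any(s <= 0 for s in self.pixel_size):
                raise ValueError("pixel_size must be strictly positive")


def _as_points(points: Sequence) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1 and pts.size == 2:
        pts = pts[None, :]
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) array of points, got shape {pts.shape}")
    return pts


def _max_triangle_area(points: np.ndarray) -> float:
    """Largest triangle area over all point triples (O(n^3); landmark sets are tiny)."""
    best = 0.0
    for (i, j, k) in itertools.combinations(range(len(points)), 3):
        p, q, r = points[i], points[j], points[k]
        area = 0.5 * abs(
            (q[0] - p[0]) * (r[1] - p[1]) - (r[0] - p[0]) * (q[1] - p[1])
        )
        best = max(best, area)
    return best


@dataclass
class ControlPointSet:
    """Paired landmark coordinates relating a source frame to a target frame."""

    source_frame: str
    target_frame: str
    source: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        self.source = _as_points(self.source)
        self.target = _as_points(self.target)
        if len(self.source) != len(self.target):
            raise ValueError("source and target must pair up one-to-one")

    def __len__(self) -> int:
        return len(self.source)

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[tuple[float, float], tuple[float, float]]],
        source_frame: str = "source",
        target_frame: str = "target",
    ) -> "ControlPointSet":
        src, dst = zip(*pairs)
        return cls(source_frame, target_frame, np.array(src, float), np.array(dst, float))

    @classmethod
    def read_csv(
        cls, path: str | Path, source_frame: str = "source", target_frame: str = "target"
    ) -> "ControlPointSet":
        """Read landmark pairs from delimited text with a required header
        ``src_x, src_y, dst_x, dst_y`` (comma or tab separated)."""
        df = pd.read_csv(path, sep=None, engine="python")
        required = ["src_x", "src_y", "dst_x", "dst_y"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"control-point file {path} lacks columns: {missing}")
        return cls(
            source_frame,
            target_frame,
            df[["src_x", "src_y"]].to_numpy(float),
            df[["dst_x", "dst_y"]].to_numpy(float),
        )


@dataclass
class AffineTransform2D:
    """A 2-D affine map ``x' = a x + b y + tx``, ``y' = c x + d y + ty``.

    ``params`` stores ``(a, b, tx, c, d, ty)``.  The transform carries the
    names of its source and target frames so chains can be validated.
    """

    params: tuple[float, float, float, float, float, float]
    source_frame: str = "source"
    target_frame: str = "target"

    def __post_init__(self) -> None:
        self.params = tuple(float(v) for v in self.params)
        if len(self.params) != 6:
            raise ValueError("an affine transform has exactly 6 parameters")
        if abs(self.determinant) < 1e-15:
            raise DegenerateGeometryError("affine transform is not invertible")

    # -- representation helpers -------------------------------------------------

    @property
    def matrix(self) -> np.ndarray:
        """The 3x3 homogeneous matrix."""
        a, b, tx, c, d, ty = self.params
        return np.array([[a, b, tx], [c, d, ty], [0.0, 0.0, 1.0]])

    @property
    def determinant(self) -> float:
        a, b, _, c, d, _ = self.params
        return a * d - b * c

    @classmethod
    def from_matrix(
        cls, m: np.ndarray, source_frame: str = "source", target_frame: str = "target"
    ) -> "AffineTransform2D":
        m = np.asarray(m, float)
        return cls(
            (m[0, 0], m[0, 1], m[0, 2], m[1, 0], m[1, 1], m[1, 2]),
            source_frame,
            target_frame,
        )

    @classmethod
    def identity(cls, frame: str = "source") -> "AffineTransform2D":
        return cls((1.0, 0.0, 0.0, 0.0, 1.0, 0.0), frame, frame)

    @classmethod
    def translation(
        cls, tx: float, ty: float, source_frame: str = "source", target_frame: str = "target"
    ) -> "AffineTransform2D":
        return cls((1.0, 0.0, tx, 0.0, 1.0, ty), source_frame, target_frame)

    # -- core operations --------------------------------------------------------

    def apply(self, points: Sequence) -> np.ndarray:
        """Map ``(n, 2)`` points from the source frame to the target frame."""
        pts = _as_points(points)
        a, b, tx, c, d, ty = self.params
        out = np.empty_like(pts)
        out[:, 0] = a * pts[:, 0] + b * pts[:, 1] + tx
        out[:, 1] = c * pts[:, 0] + d * pts[:, 1] + ty
        return out

    def inverse(self) -> "AffineTransform2D":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform2D.from_matrix(inv, self.target_frame, self.source_frame)

    # -- serialization ----------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "source_frame": self.source_frame,
            "target_frame": self.target_frame,
            "params": list(self.params),
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def read_json(cls, path: str | Path) -> "AffineTransform2D":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["params"]), d["source_frame"], d["target_frame"])


def fit_affine(cp: ControlPointSet) -> AffineTransform2D:
    """Fit the affine transform mapping ``cp.source`` onto ``cp.target``.

    With exactly 3 non-collinear pairs the transform interpolates the pairs
    exactly; with more pairs it is the least-squares minimizer of the summed
    squared target-space residuals.
    """
    n = len(cp)
    if n < 3:
        raise InsufficientPointsError(f"affine fitting needs >= 3 pairs, got {n}")
    if _max_triangle_area(cp.source) <= COLLINEARITY_TOL:
        raise DegenerateGeometryError("source landmarks are collinear")
    design = np.column_stack([cp.source, np.ones(n)])
    if n == 3:
        sol_x = np.linalg.solve(design, cp.target[:, 0])
        sol_y = np.linalg.solve(design, cp.target[:, 1])
    else:
        sol_x, *_ = np.linalg.lstsq(design, cp.target[:, 0], rcond=None)
        sol_y, *_ = np.linalg.lstsq(design, cp.target[:, 1], rcond=None)
    return AffineTransform2D(
        (sol_x[0], sol_x[1], sol_x[2], sol_y[0], sol_y[1], sol_y[2]),
        cp.source_frame,
        cp.target_frame,
    )


def apply_transform(t: AffineTransform2D, points: Sequence) -> np.ndarray:
    """Functional alias for :meth:`AffineTransform2D.apply`."""
    return t.apply(points)


def compose(outer: AffineTransform2D, inner: AffineTransform2D) -> AffineTransform2D:
    """The chained transform ``outer ∘ inner`` (apply ``inner`` first).

    Raises :class:`FrameChainError` if ``inner.target_frame`` is not
    ``outer.source_frame``.
    """
    if inner.target_frame != outer.source_frame:
        raise FrameChainError(
            f"cannot chain {inner.source_frame}->{inner.target_frame} "
            f"into {outer.source_frame}->{outer.target_frame}"
        )
    return AffineTransform2D.from_matrix(
        outer.matrix @ inner.matrix, inner.source_frame, outer.target_frame
    )


@dataclass
class RegistrationError:
    """Per-axis registration error summary, in micrometers.

    ``mean_x``/``mean_y`` are means of the absolute per-axis deviations;
    ``sd_x``/``sd_y`` are their sample standard deviations (n−1 denominator,
    zero for a single landmark); ``n`` is the number of landmarks (or, for a
    propagated error, the number of chained steps).
    """

    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for v in (self.mean_x, self.mean_y, self.sd_x, self.sd_y):
            if v < 0:
                raise ValueError("error summaries must be non-negative")


def estimate_error(deviations: Sequence) -> RegistrationError:
    """Summarize signed per-landmark deviations ``(dx, dy)`` in micrometers.

    Deviations enter signed but are summarized as absolute values per axis:
    mean of ``|dx|`` and ``|dy|``, with the sample SD (n−1) of the absolute
    deviations.  A single landmark has SD 0 by convention.
    """
    dev = _as_points(deviations)
    if len(dev) == 0:
        raise ValueError("at least one deviation is required")
    absdev = np.abs(dev)
    mean = absdev.mean(axis=0)
    if len(dev) == 1:
        sd = np.zeros(2)
    else:
        sd = absdev.std(axis=0, ddof=1)
    return RegistrationError(mean[0], mean[1], sd[0], sd[1], len(dev))


def self_consistency_error(points_a: Sequence, points_b: Sequence) -> float:
    """Mean Euclidean distance between paired original and re-registered points.

    Used to quantify the operator-induced error of manual landmark picking by
    registering an image onto itself several times.
    """
    a = _as_points(points_a)
    b = _as_points(points_b)
    if len(a) != len(b):
        raise ValueError("point lists must have equal length")
    if len(a) == 0:
        raise ValueError("at least one pair is required")
    return float(np.hypot(*(a - b).T).mean())


def propagate_errors(steps: Sequence[RegistrationError]) -> RegistrationError:
    """Worst-case additive propagation across chained registration steps.

    Per axis, the combined mean is the sum of the per-step means (errors
    assumed to add), and the combined SD adds the per-step SDs in quadrature
    (independent steps).  ``n`` of the result is the number of steps.
    """
    steps = list(steps)
    if not steps:
        raise ValueError("at least one step is required")
    return RegistrationError(
        mean_x=sum(s.mean_x for s in steps),
        mean_y=sum(s.mean_y for s in steps),
        sd_x=math.sqrt(sum(s.sd_x**2 for s in steps)),
        sd_y=math.sqrt(sum(s.sd_y**2 for s in steps)),
        n=len(steps),
    )


def dpi_to_micrometers(dpi: float) -> float:
    """Physical pixel pitch in micrometers for a scan resolution in dots/inch."""
    if dpi <= 0:
        raise ValueError("dpi must be positive")
    return MICROMETERS_PER_INCH / dpi
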