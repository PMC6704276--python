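"""Synthetic fixtures for every stage of the pipeline.

No public dataset accompanies the workflow, so all tests and demonstrations
run on phantoms that emulate the acquisition: a regular MSI grid (70 μm
pitch, nominal m/z 350–1600) partitioned into ``k`` spatially contiguous
regions with distinct sparse non-negative spectral signatures plus truncated
Gaussian noise; optical/H&E image pairs carrying fiducial spots placed by
known ground-truth affine transforms (with optional landmark-picking
jitter); and protein LFQ tables with planted exclusively-regulated markers.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import AffineTransform2D, ControlPointSet
from .msi import MSIDataset
from .proteomics import ProteinTable, RegulationCall
from .roi import LabelImage

logger = logging.getLogger(__name__)


def default_true_transforms() -> dict:
    """Ground-truth transforms emulating the physical setup: the MSI pitch
    (70 μm) over the optical pixel size (~2.08 μm) gives a ~33.6× upscale;
    optical → H&E is a small rigid-ish motion (same scanner, restained slide)."""
    msi_to_optical = AffineTransform2D(
        (33.72, 0.45, 120.0, -0.38, 33.59, 95.0), "msi", "optical"
    )
    optical_to_he = AffineTransform2D(
        (0.9995, 0.018, 6.0, -0.018, 0.9995, -4.0), "optical", "he"
    )
    return {("msi", "optical"): msi_to_optical, ("optical", "he"): optical_to_he}


@dataclass
class PhantomSpec:
    """Parameters of the synthetic study.

    Defaults mirror the acquisition: 40×40 grid at 70 μm pitch, 3 planted
    clusters, 60 spectral bins spanning m/z 350–1600, sparse signatures with
    peak amplitude ``signature_separation`` over noise SD ``noise_sd``.
    """

    grid_shape: tuple[int, int] = (40, 40)  # (rows, cols)
    pitch: float = 70.0
    k_true: int = 3
    n_channels: int = 60
    mz_range: tuple[float, float] = (350.0, 1600.0)
    signature_separation: float = 5.0
    noise_sd: float = 0.5
    fiducial_count: int = 5
    true_transforms: dict = field(default_factory=default_true_transforms)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid_shape) < 1:
            raise ValueError("grid_shape must be positive")
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.noise_sd < 0 or self.signature_separation < 0:
            raise ValueError("noise_sd and signature_separation must be >= 0")
        if self.fiducial_count < 3:
            raise ValueError("at least 3 fiducials are required")


def _signatures(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Sparse non-negative signatures: a shared low baseline plus a few
    cluster-exclusive dominant channels, so the factorization is identifiable."""
    n_peaks = max(2, spec.n_channels // (4 * spec.k_true))
    baseline = 0.2 + 0.1 * rng.random(spec.n_channels)
    sig = np.tile(baseline, (spec.k_true, 1))
    channels = rng.permutation(spec.n_channels)
    for r in range(spec.k_true):
        own = channels[r * n_peaks: (r + 1) * n_peaks]
        sig[r, own] += spec.signature_separation * (0.8 + 0.4 * rng.random(len(own)))
    return sig


def make_msi_phantom(spec: PhantomSpec) -> tuple[MSIDataset, LabelImage]:
    """A gridded MSI dataset with ``k_true`` contiguous regions.

    Regions are the Voronoi cells of ``k_true`` seeded centers (hence
    contiguous); pixel spectra are the region signature plus truncated
    Gaussian noise.  Returns the dataset and the ground-truth label image
    (labels 1..k over the full grid).
    """
    rows, cols = spec.grid_shape
    if spec.k_true > rows * cols:
        raise ValueError("more clusters than pixels")
    rng = np.random.default_rng(spec.seed)
    centers = np.column_stack(
        [rng.uniform(0, cols, spec.k_true), rng.uniform(0, rows, spec.k_true)]
    )
    yy, xx = np.mgrid[0:rows, 0:cols]
    pix = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    d2 = ((pix[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    region = d2.argmin(axis=1)  # 0..k-1
    sig = _signatures(spec, rng)
    spectra = sig[region] + rng.normal(0.0, spec.noise_sd, size=(rows * cols, spec.n_channels))
    spectra = np.clip(spectra, 0.0, None)  # truncate at 0 to keep non-negativity
    mz_axis = np.linspace(*spec.mz_range, spec.n_channels)
    ds = MSIDataset(pix.astype(int), spectra, mz_axis, pitch=spec.pitch)
    truth = LabelImage(frame="msi", values=(region + 1).reshape(rows, cols))
    return ds, truth


@dataclass
class RegistrationPhantom:
    """Fiducial/landmark coordinates in every frame plus the generating truth."""

    landmarks: dict  # frame name -> (n, 2) float array
    control_points: dict  # (src, dst) frame pair -> ControlPointSet (with jitter)
    true_transforms: dict  # (src, dst) frame pair -> AffineTransform2D
    images: dict  # frame name -> uint8 raster with fiducial spots drawn


def _draw_spots(shape: tuple[int, int], points: np.ndarray, radius: int = 4) -> np.ndarray:
    img = np.zeros(shape, dtype=np.uint8)
    yy, xx = np.mgrid[0: shape[0], 0: shape[1]]
    for x, y in points:
        img[(xx - x) ** 2 + (yy - y) ** 2 <= radius**2] = 255
    return img


def make_registration_phantom(
    spec: PhantomSpec,
    jitter_sd: float = 0.0,
    image_shape: tuple[int, int] = (1600, 1600),
) -> RegistrationPhantom:
    """Landmark sets related exactly (or with seeded Gaussian jitter, in
    target-frame pixels) by the spec's ground-truth transforms, plus optical
    and H&E rasters with the fiducial spots drawn in."""
    t_mo = spec.true_transforms[("msi", "optical")]
    t_oh = spec.true_transforms[("optical", "he")]
    rng = np.random.default_rng(spec.seed + 1)
    rows, cols = spec.grid_shape
    n = spec.fiducial_count
    msi_pts = np.column_stack([rng.uniform(1, cols - 1, n), rng.uniform(1, rows - 1, n)])
    optical_pts = t_mo.apply(msi_pts)
    he_pts = t_oh.apply(optical_pts)
    jitter = rng.normal(0.0, jitter_sd, size=(2, n, 2)) if jitter_sd > 0 else np.zeros((2, n, 2))
    cps = {
        ("msi", "optical"): ControlPointSet("msi", "optical", msi_pts, optical_pts + jitter[0]),
        ("optical", "he"): ControlPointSet("optical", "he", optical_pts, he_pts + jitter[1]),
    }
    images = {
        "optical": _draw_spots(image_shape, optical_pts),
        "he": _draw_spots(image_shape, he_pts),
    }
    return RegistrationPhantom(
        landmarks={"msi": msi_pts, "optical": optical_pts, "he": he_pts},
        control_points=cps,
        true_transforms=dict(spec.true_transforms),
        images=images,
    )


def write_control_points(cp: ControlPointSet, path: str | Path) -> None:
    """Write a control-point set in the registration CSV dialect."""
    df = pd.DataFrame(
        {
            "src_x": cp.source[:, 0],
            "src_y": cp.source[:, 1],
            "dst_x": cp.target[:, 0],
            "dst_y": cp.target[:, 1],
        }
    )
    df.to_csv(path, index=False)


def make_protein_phantom(
    n_proteins: int = 1040,
    segments: int = 3,
    planted_per_segment: int = 10,
    effect_size: float = 3.0,
    noise_sd: float = 0.0,
    base_mean: float = 25.0,
    base_sd: float = 2.0,
    seed: int = 0,
) -> tuple[ProteinTable, list[RegulationCall]]:
    """A protein LFQ table with planted exclusively-regulated markers.

    For every segment, ``planted_per_segment`` proteins get their log2
    intensity in that segment shifted by ``+effect_size`` (over-expressed
    markers) and another ``planted_per_segment`` by ``-effect_size``
    (under-expressed).  The remaining proteins are expressed equally across
    segments; ``noise_sd`` adds exchangeable per-entry Gaussian noise on the
    log2 scale (0 by default, so the non-planted rows stay constant and the
    planted truth is exactly recoverable).  Returns the table and the ground
    truth as regulation calls.
    """
    if 2 * planted_per_segment * segments > n_proteins:
        raise ValueError("planted markers exceed the number of proteins")
    rng = np.random.default_rng(seed)
    segment_names = [f"segment_{i + 1}" for i in range(segments)]
    ids = [f"P{i + 1:05d}" for i in range(n_proteins)]
    base = rng.normal(base_mean, base_sd, size=n_proteins)
    log_int = np.tile(base[:, None], (1, segments))
    truth: list[RegulationCall] = []
    row = 0
    for s, name in enumerate(segment_names):
        for direction, sign in (("over", 1.0), ("under", -1.0)):
            for _ in range(planted_per_segment):
                log_int[row, s] += sign * effect_size
                truth.append(RegulationCall(ids[row], name, direction))
                row += 1
    if noise_sd > 0:
        log_int = log_int + rng.normal(0.0, noise_sd, size=log_int.shape)
    intensities = pd.DataFrame(2.0**log_int, index=pd.Index(ids, name="protein_id"),
                               columns=segment_names)
    flags = pd.DataFrame(
        False, index=intensities.index,
        columns=["reverse", "only_identified_by_site", "potential_contaminant"],
    )
    return ProteinTable(intensities=intensities, flags=flags), truth


def write_maxquant(table: ProteinTable, path: str | Path) -> None:
    """Write a ProteinTable in the MaxQuant proteinGroups TSV dialect."""
    df = pd.DataFrame({"Protein IDs": table.protein_ids})
    for col, name in (
        ("Reverse", "reverse"),
        ("Only identified by site", "only_identified_by_site"),
        ("Potential contaminant", "potential_contaminant"),
    ):
        df[col] = np.where(table.flags[name].to_numpy(), "+", "")
    for seg in table.segment_names:
        df[f"LFQ intensity {seg}"] = table.intensities[seg].to_numpy()
    df.to_csv(path, sep="\t", index=False)
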