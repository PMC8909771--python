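"""Threshold/morphology segmentation of phantom CT scenes.

Produces the structure masks and marker centroids the guidance pipeline
consumes: body, bone, liver, vessels, radiopaque skin markers (and
optionally the spleen), plus seeded semi-automatic tumor segmentation by
constrained region growing. The segmenter is deliberately simple — a
contrast-ladder pipeline validated only on synthetic phantoms — because the
pipeline contract downstream needs masks and marker points, not a
clinical-grade organ segmenter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import BinaryMask, Volume, voxel_from_world, world_from_voxel


class SegmentationError(RuntimeError):
    """Segmentation could not produce a usable result (e.g. empty body)."""


class InsufficientFiducialsError(RuntimeError):
    """Fewer marker components than the registration floor requires."""


@dataclass
class HUThresholds:
    """HU cutoffs for the phantom contrast ladder (air < soft < liver <
    spleen < vessels < bone < markers)."""

    body_min: float = -400.0
    liver_lo: float = 55.0
    liver_hi: float = 80.0
    spleen_lo: float = 85.0
    spleen_hi: float = 115.0
    vessel_lo: float = 120.0
    vessel_hi: float = 300.0
    bone_lo: float = 350.0
    bone_hi: float = 1500.0
    marker_min: float = 1500.0


@dataclass
class SegmentationResult:
    """Per-structure masks plus labelled marker centroids (world mm)."""

    body: BinaryMask
    bone: BinaryMask
    liver: BinaryMask
    vessels: BinaryMask
    markers: BinaryMask
    spleen: BinaryMask | None
    marker_centroids: np.ndarray
    marker_labels: list[str] = field(default_factory=list)


def _largest_component(bits: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(bits)
    if n == 0:
        return np.zeros_like(bits, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (int(np.argmax(sizes)) + 1)


def segment_auto(volume: Volume,
                 thresholds: HUThresholds | None = None) -> SegmentationResult:
    """Automatic segmentation of body, bone, liver, vessels, spleen, markers.

    Threshold + connected-component + morphological cleanup: the body is
    the largest filled non-air component; the liver candidate is the
    largest component in the liver HU band inside the body, hole-filled so
    that hypodense tumors and enhanced vessels stay inside it; marker
    components sit above the marker threshold on the body surface.

    Raises :class:`SegmentationError` if no body is found.
    """
    th = thresholds or HUThresholds()
    hu = volume.intensities
    grid = volume

    body_bits = _largest_component(hu > th.body_min)
    if not body_bits.any():
        raise SegmentationError("empty body mask: volume contains no tissue")
    body_bits = ndimage.binary_fill_holes(body_bits)
    body = BinaryMask(bits=body_bits, grid=grid)

    bone = BinaryMask(bits=(hu >= th.bone_lo) & (hu <= th.bone_hi) & body_bits,
                      grid=grid)

    liver_band = (hu >= th.liver_lo) & (hu <= th.liver_hi) & body_bits
    liver_bits = _largest_component(liver_band)
    liver_bits = ndimage.binary_closing(liver_bits, iterations=2)
    liver_bits = ndimage.binary_fill_holes(liver_bits) & body_bits
    liver = BinaryMask(bits=liver_bits, grid=grid)

    near_liver = ndimage.binary_dilation(liver_bits, iterations=2)
    vessels = BinaryMask(
        bits=(hu >= th.vessel_lo) & (hu <= th.vessel_hi) & near_liver,
        grid=grid)

    spleen_band = (hu >= th.spleen_lo) & (hu <= th.spleen_hi) & body_bits & ~liver_bits
    spleen_bits = _largest_component(spleen_band)
    spleen = BinaryMask(bits=spleen_bits, grid=grid) if spleen_bits.any() else None

    interior = ndimage.binary_erosion(body_bits, iterations=3)
    marker_bits = (hu >= th.marker_min) & ~interior
    markers = BinaryMask(bits=marker_bits, grid=grid)

    centroids, labels = marker_centroids(markers, volume)
    return SegmentationResult(body=body, bone=bone, liver=liver,
                              vessels=vessels, markers=markers, spleen=spleen,
                              marker_centroids=centroids, marker_labels=labels)


def marker_centroids(marker_mask: BinaryMask,
                     volume: Volume) -> tuple[np.ndarray, list[str]]:
    """Intensity-weighted centroid of each marker component, in world mm.

    Labels are assigned by a deterministic lexicographic sort of the
    centroid coordinates — correspondence with the tracker's markers is
    established downstream by geometry, so labels only need determinism.

    Raises :class:`InsufficientFiducialsError` below 3 components.
    """
    lab, n = ndimage.label(marker_mask.bits)
    if n < 3:
        raise InsufficientFiducialsError(
            f"need >= 3 marker components for registration, found {n}")
    weights = volume.intensities - volume.intensities.min()
    coms = ndimage.center_of_mass(weights, lab, index=np.arange(1, n + 1))
    world = world_from_voxel(volume, np.asarray(coms))
    order = np.lexsort((world[:, 2], world[:, 1], world[:, 0]))
    world = world[order]
    labels = [f"F{i:02d}" for i in range(n)]
    return world, labels


def segment_tumor_seeded(volume: Volume, seed_point, band: float = 15.0,
                         max_radius: float = 30.0,
                         body: BinaryMask | None = None) -> BinaryMask:
    """Semi-automatic tumor segmentation by constrained region growing.

    Grows from the seed over voxels with ``|HU - HU(seed)| <= band`` within
    ``max_radius`` mm of the seed, keeps the connected component containing
    the seed and applies a morphological closing.

    Raises ``ValueError`` if the seed lies outside the scanned body.
    """
    seed_idx = np.rint(voxel_from_world(volume, seed_point)).astype(int)
    if np.any(seed_idx < 0) or np.any(seed_idx >= np.asarray(volume.shape)):
        raise ValueError(f"seed point {seed_point} outside the volume")
    if body is not None and not body.bits[tuple(seed_idx)]:
        raise ValueError(f"seed point {seed_point} outside the body")

    hu0 = float(volume.intensities[tuple(seed_idx)])
    grow = np.abs(volume.intensities - hu0) <= band

    # metric radius constraint about the seed
    ii, jj, kk = np.indices(volume.shape, sparse=True)
    sp = volume.spacing
    d2 = (((ii - seed_idx[0]) * sp[0]) ** 2
          + ((jj - seed_idx[1]) * sp[1]) ** 2
          + ((kk - seed_idx[2]) * sp[2]) ** 2)
    grow &= d2 <= max_radius**2

    lab, _ = ndimage.label(grow)
    comp = lab == lab[tuple(seed_idx)]
    if lab[tuple(seed_idx)] == 0:
        # degenerate: band excludes even the seed's neighbourhood
        comp = np.zeros(volume.shape, dtype=bool)
        comp[tuple(seed_idx)] = True
        return BinaryMask(bits=comp, grid=volume)
    comp = ndimage.binary_closing(comp, iterations=1)
    comp &= d2 <= max_radius**2
    return BinaryMask(bits=comp, grid=volume)
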