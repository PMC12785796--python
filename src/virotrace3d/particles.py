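"""Viral-particle detection and per-particle measurements.

Spots are detected as local maxima of a (negated) Laplacian-of-Gaussian
response, segmented by a seeded watershed restricted to the super-level
set of a calibrated intensity threshold, and measured for volume,
intensity, nuclear ratio (NR) and distance to the nuclear boundary.

Conventions (each isolated here so it can be swapped):

* a voxel is particle foreground iff its intensity is **>= threshold**;
* the particle-to-nucleus distance is measured from the particle
  *centroid* to the nearest nucleus voxel centre, in anisotropic
  physical units (um), and is forced to 0 whenever NR > 0;
* the normalized distance divides by ``D_max``, the maximum
  nucleus-to-membrane distance within the owning cell, and is clipped
  to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .core import log

DEFAULT_CALIBRATION_THRESHOLDS = (300, 400, 500, 600, 700, 800)


@dataclass
class ParticleParams:
    """Detector settings.

    ``log_sigma`` is the per-axis LoG scale in voxels, matched to the
    diffraction-limited spot size on the anisotropic grid. ``threshold``
    is the intensity level (same scale as the particle channel) used for
    final segmentation; ``calibration_thresholds`` is the sweep used to
    pick it on control samples.
    """

    log_sigma: tuple[float, float, float] = (0.6, 1.3, 1.3)
    threshold: float = 600.0
    calibration_thresholds: tuple[float, ...] = DEFAULT_CALIBRATION_THRESHOLDS
    min_volume: int = 1
    response_floor: float = 100.0
    peak_min_distance: int = 2

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.log_sigma):
            raise ValueError("LoG scales must be positive")
        if self.threshold <= 0 or any(t <= 0 for t in self.calibration_thresholds):
            raise ValueError("thresholds must be positive")


# ---------------------------------------------------------------- detection


def log_response(volume: np.ndarray, sigma: tuple[float, float, float]) -> np.ndarray:
    """Scale-normalized negated LoG response; bright blobs become maxima."""
    vol = np.asarray(volume, dtype=float)
    # sigma**2 normalization uses the geometric mean of the anisotropic scales
    norm = float(np.prod(sigma)) ** (2.0 / len(sigma))
    return -norm * ndimage.gaussian_laplace(vol, sigma=sigma)


def detect_centroids(volume: np.ndarray, params: ParticleParams) -> np.ndarray:
    """Detect spot centroids as LoG-response maxima above the floor.

    Returns an ``(n, 3)`` float array of ``(z, y, x)`` voxel coordinates
    (integer-valued: maxima of the discrete response). Empty array when
    nothing is found.
    """
    response = log_response(volume, params.log_sigma)
    peaks = peak_local_max(
        response,
        min_distance=params.peak_min_distance,
        threshold_abs=params.response_floor,
        exclude_border=False,
    )
    return peaks.astype(float)


def segment_particles(
    volume: np.ndarray, centroids: np.ndarray, threshold: float
) -> np.ndarray:
    """Seeded watershed on the >= ``threshold`` super-level set.

    Each seed inside the foreground yields one label; foreground voxels
    whose connected component contains no seed are discarded. Seeds on
    sub-threshold voxels are dropped (that spot is "not detected" at
    this threshold).
    """
    vol = np.asarray(volume)
    mask = vol >= threshold
    labels = np.zeros(vol.shape, dtype=np.int32)
    if centroids is None or len(centroids) == 0 or not mask.any():
        return labels
    markers = np.zeros(vol.shape, dtype=np.int32)
    next_id = 1
    for zyx in np.asarray(centroids):
        idx = tuple(np.round(zyx).astype(int))
        if all(0 <= i < s for i, s in zip(idx, vol.shape)) and mask[idx]:
            if markers[idx] == 0:
                markers[idx] = next_id
                next_id += 1
    if next_id == 1:
        return labels
    labels = watershed(-vol.astype(float), markers=markers, mask=mask)
    # drop foreground components not reached from any seed: watershed
    # already leaves them 0, but guard against isolated marker plateaus
    return labels.astype(np.int32)


def sweep_thresholds(
    volume: np.ndarray,
    centroids: np.ndarray,
    thresholds: tuple[float, ...] = DEFAULT_CALIBRATION_THRESHOLDS,
) -> pd.Series:
    """Particle count at each calibration threshold (counts are
    non-increasing in the threshold because super-level sets nest)."""
    counts = {}
    for t in sorted(thresholds):
        labels = segment_particles(volume, centroids, t)
        counts[t] = int(labels.max())
    return pd.Series(counts, name="n_particles").rename_axis("threshold")


# ------------------------------------------------------------- measurements


def compute_nuclear_ratio(particle_mask: np.ndarray, nucleus_mask: np.ndarray) -> float:
    """NR = fraction of the particle's voxel volume inside the nucleus."""
    particle_mask = np.asarray(particle_mask, dtype=bool)
    total = int(particle_mask.sum())
    if total == 0:
        raise ValueError("empty particle mask: nuclear ratio undefined")
    inside = int((particle_mask & np.asarray(nucleus_mask, dtype=bool)).sum())
    return inside / total


def nucleus_distance_field(
    nucleus_mask: np.ndarray, spacing: tuple[float, float, float]
) -> np.ndarray:
    """Anisotropic distance (um) from every voxel centre to the nearest
    nucleus voxel centre; 0 inside the nucleus."""
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if not nucleus_mask.any():
        return np.full(nucleus_mask.shape, np.inf)
    return ndimage.distance_transform_edt(~nucleus_mask, sampling=spacing)


def max_nucleus_to_membrane_distance(
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    spacing: tuple[float, float, float],
) -> float:
    """``D_max``: maximum over the cell's voxels of distance-to-nucleus."""
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        return 0.0
    field = nucleus_distance_field(nucleus_mask, spacing)
    return float(field[cell_mask].max())


def compute_distances(
    centroid: np.ndarray,
    nuclear_ratio: float,
    nucleus_mask: np.ndarray,
    cell_mask: np.ndarray,
    spacing: tuple[float, float, float],
    d_max: float | None = None,
) -> tuple[float, float]:
    """Raw and normalized centroid-to-nuclear-boundary distance.

    ``x_raw`` is the exact minimum anisotropic Euclidean distance from the
    (possibly fractional) centroid to any nucleus voxel centre, forced to
    0 when NR > 0 or the centroid voxel lies inside the nucleus. ``x_norm``
    divides by ``d_max`` (computed here when not supplied) and is clipped
    to [0, 1]; a degenerate cell with ``d_max == 0`` yields 0 with a
    warning.
    """
    centroid = np.asarray(centroid, dtype=float)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    spacing_arr = np.asarray(spacing, dtype=float)

    idx = tuple(np.clip(np.round(centroid).astype(int), 0, np.array(nucleus_mask.shape) - 1))
    if nuclear_ratio > 0 or nucleus_mask[idx]:
        x_raw = 0.0
    elif not nucleus_mask.any():
        x_raw = float("inf")
    else:
        coords = np.argwhere(nucleus_mask) * spacing_arr
        tree = cKDTree(coords)
        x_raw, _ = tree.query(centroid * spacing_arr)
        x_raw = float(x_raw)
    if d_max is None:
        d_max = max_nucleus_to_membrane_distance(cell_mask, nucleus_mask, spacing)
    if d_max <= 0:
        if x_raw > 0:
            log.warning("degenerate cell (D_max = 0); normalized distance set to 0")
        return x_raw, 0.0
    return x_raw, float(np.clip(x_raw / d_max, 0.0, 1.0))


def assign_particles_to_cells(
    particle_labels: np.ndarray, cells: np.ndarray
) -> tuple[dict[int, int], int]:
    """Map particle label -> owning cell label by centroid containment.

    Particles whose centroid falls on background are excluded from
    per-cell analyses; the second return value tallies them for QC.
    """
    particle_labels = np.asarray(particle_labels)
    cells = np.asarray(cells)
    owners: dict[int, int] = {}
    unassigned = 0
    for p in np.unique(particle_labels):
        if p == 0:
            continue
        centroid = np.mean(np.argwhere(particle_labels == p), axis=0)
        idx = tuple(np.round(centroid).astype(int))
        owner = int(cells[idx])
        if owner == 0:
            unassigned += 1
        else:
            owners[int(p)] = owner
    return owners, unassigned


def measure_particles(
    volume: np.ndarray,
    particle_labels: np.ndarray,
    cells: np.ndarray,
    nuclei: np.ndarray,
    nucleus_of_cell: dict[int, int],
    spacing: tuple[float, float, float],
    timepoint: int = 0,
) -> pd.DataFrame:
    """Per-particle measurement table.

    One row per detected particle owned by a cell that has an associated
    nucleus: centroid, voxel volume, mean/total intensity, NR, raw and
    normalized distance. ``nucleus_of_cell`` maps cell label -> nucleus
    label (from segmentation association). Centroid-in-background
    particles are tallied but not measured.
    """
    volume = np.asarray(volume)
    particle_labels = np.asarray(particle_labels)
    owners, n_unassigned = assign_particles_to_cells(particle_labels, cells)
    if n_unassigned:
        log.info("%d particles outside any cell (QC tally)", n_unassigned)

    dmax_cache: dict[int, float] = {}
    nucmask_cache: dict[int, np.ndarray] = {}
    rows = []
    for p, cell_label in sorted(owners.items()):
        nuc_label = nucleus_of_cell.get(cell_label)
        if nuc_label is None:
            continue
        pmask = particle_labels == p
        volume_vox = int(pmask.sum())
        if volume_vox == 0:
            continue
        if nuc_label not in nucmask_cache:
            nucmask_cache[nuc_label] = nuclei == nuc_label
        nmask = nucmask_cache[nuc_label]
        if cell_label not in dmax_cache:
            dmax_cache[cell_label] = max_nucleus_to_membrane_distance(
                cells == cell_label, nmask, spacing
            )
        centroid = np.mean(np.argwhere(pmask), axis=0)
        nr = compute_nuclear_ratio(pmask, nmask)
        x_raw, x_norm = compute_distances(
            centroid, nr, nmask, cells == cell_label, spacing, d_max=dmax_cache[cell_label]
        )
        intensities = volume[pmask]
        rows.append(
            {
                "particle_id": int(p),
                "timepoint": timepoint,
                "cell_label": int(cell_label),
                "nucleus_label": int(nuc_label),
                "z": centroid[0],
                "y": centroid[1],
                "x": centroid[2],
                "volume_vox": volume_vox,
                "mean_intensity": float(intensities.mean()),
                "total_intensity": float(intensities.sum()),
                "nuclear_ratio": nr,
                "x_raw_um": x_raw,
                "x_norm": x_norm,
            }
        )
    columns = [
        "particle_id", "timepoint", "cell_label", "nucleus_label",
        "z", "y", "x", "volume_vox", "mean_intensity", "total_intensity",
        "nuclear_ratio", "x_raw_um", "x_norm",
    ]
    df = pd.DataFrame(rows, columns=columns)
    df.attrs["n_unassigned"] = n_unassigned
    return df
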