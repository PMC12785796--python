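"""Nucleus and cell instance segmentation.

Nuclei are segmented per timepoint in two stages: a planar instance
segmentation on the maximum-intensity projection (classical
blur/Otsu/seeded-watershed backend by default; any callable mapping a
2D image to a 2D label image can be plugged in), fused with a 3D
threshold-based mask obtained by the downscale -> blur -> Otsu ->
resize -> z-hole-fill chain. Cells are segmented from the
cytoplasmic/membrane marker channel with the same thresholding chain
and partitioned among their nuclei; nucleus-free cells are dropped and
each retained cell is expanded to fully contain its nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed
from skimage.transform import downscale_local_mean, resize

from .core import ChannelStack, log


@dataclass
class SegmentationParams:
    """Parameters of the two-stage segmentation.

    Defaults target full-resolution acquisitions (3428 x 3428 XY grids);
    ``desk_scale`` returns a profile for small synthetic fields, scaled
    by the ~27x linear resolution ratio.
    """

    gaussian_sigma: float = 3.0  # in-plane blur of the downscaled volume
    downscale_factor: int = 4  # in-plane local-mean downscale
    min_nucleus_volume: int = 10_000  # voxels; objects below are excluded
    min_cell_volume: int = 10_000
    planar_sigma: float = 2.0  # blur for the classical planar backend
    planar_min_distance: int = 10  # seed separation for watershed splitting
    planar_backend: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.gaussian_sigma <= 0 or self.planar_sigma <= 0:
            raise ValueError("blur sigmas must be positive")
        if self.downscale_factor < 1:
            raise ValueError("downscale factor must be >= 1")
        if self.min_nucleus_volume < 0 or self.min_cell_volume < 0:
            raise ValueError("minimum volumes must be >= 0")

    @classmethod
    def desk_scale(cls) -> "SegmentationParams":
        """Profile for ~128-pixel-wide synthetic fields."""
        return cls(
            gaussian_sigma=1.0,
            downscale_factor=1,
            min_nucleus_volume=500,
            min_cell_volume=500,
            planar_sigma=1.0,
            planar_min_distance=8,
        )


# ----------------------------------------------------------------- helpers


def otsu_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold by exhaustive between-class-variance maximization.

    The histogram uses ``nbins`` equal-width bins over the data range
    (for 8-bit integer data this is one bin per gray level). Foreground
    is ``image > threshold``. The returned level is the bin centre
    maximizing the between-class variance; the lowest maximizer wins on
    ties.
    """
    values = np.asarray(image).ravel()
    if values.size == 0:
        raise ValueError("cannot threshold an empty image")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise ValueError("constant image: Otsu threshold undefined")
    if np.issubdtype(values.dtype, np.integer) and hi - lo < nbins:
        # one bin per gray level so the returned level is an exact gray value
        edges = np.arange(lo, hi + 2) - 0.5
        counts, _ = np.histogram(values, bins=edges)
        centers = np.arange(lo, hi + 1, dtype=float)
    else:
        counts, edges = np.histogram(values, bins=nbins, range=(lo, hi))
        centers = (edges[:-1] + edges[1:]) / 2.0
    w = counts / counts.sum()
    # cumulative class probability and mean for thresholds after each bin
    omega0 = np.cumsum(w)
    mu_t = np.cumsum(w * centers)
    mu_total = mu_t[-1]
    omega1 = 1.0 - omega0
    valid = (omega0 > 0) & (omega1 > 0)
    sigma_b = np.zeros_like(omega0)
    sigma_b[valid] = (mu_total * omega0[valid] - mu_t[valid]) ** 2 / (
        omega0[valid] * omega1[valid]
    )
    return float(centers[int(np.argmax(sigma_b))])


def fill_holes_z(mask: np.ndarray) -> np.ndarray:
    """Fill background runs along z that are bounded by foreground in the
    same (y, x) column; in-plane holes are untouched."""
    mask = np.asarray(mask, dtype=bool)
    seen_above = np.maximum.accumulate(mask, axis=0)
    seen_below = np.maximum.accumulate(mask[::-1], axis=0)[::-1]
    return seen_above & seen_below


def filter_small_instances(labels: np.ndarray, min_volume: int) -> np.ndarray:
    """Zero out instances with voxel volume strictly below ``min_volume``."""
    labels = np.asarray(labels)
    out = labels.copy()
    counts = np.bincount(labels.ravel())
    for lbl in np.nonzero(counts < min_volume)[0]:
        if lbl:
            out[labels == lbl] = 0
    return out


def _threshold_mask_3d(volume: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """downscale -> blur -> Otsu -> resize -> z-hole-fill binary chain."""
    volume = np.asarray(volume, dtype=float)
    f = params.downscale_factor
    small = downscale_local_mean(volume, (1, f, f)) if f > 1 else volume
    blurred = ndimage.gaussian_filter(
        small, sigma=(0, params.gaussian_sigma, params.gaussian_sigma)
    )
    try:
        thr = otsu_threshold(blurred)
    except ValueError:
        log.warning("constant volume: empty threshold mask returned")
        return np.zeros(volume.shape, dtype=bool)
    binary = blurred > thr
    if f > 1:
        binary = (
            resize(binary.astype(float), volume.shape, order=0, anti_aliasing=False)
            > 0.5
        )
    return fill_holes_z(binary)


# -------------------------------------------------------------- operations


def max_project(stack: ChannelStack, role: str, t: int) -> np.ndarray:
    """Pixelwise maximum over z of one channel at one timepoint."""
    return stack.channel(role, t).max(axis=0)


def segment_nuclei_planar(
    mip: np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Instance-segment nuclei in a 2D projection.

    Default classical backend: Gaussian blur, Otsu threshold,
    distance-transform-seeded watershed to split touching nuclei. A
    blank image yields an empty labeling.
    """
    params = params or SegmentationParams()
    if params.planar_backend is not None:
        return np.asarray(params.planar_backend(mip)).astype(np.int32)
    mip = np.asarray(mip, dtype=float)
    blurred = ndimage.gaussian_filter(mip, params.planar_sigma)
    try:
        thr = otsu_threshold(blurred)
    except ValueError:
        return np.zeros(mip.shape, dtype=np.int32)
    binary = blurred > thr
    if not binary.any():
        return np.zeros(mip.shape, dtype=np.int32)
    distance = ndimage.distance_transform_edt(binary)
    seeds = peak_local_max(
        distance,
        min_distance=params.planar_min_distance,
        labels=binary,
        exclude_border=False,
    )
    markers = np.zeros(mip.shape, dtype=np.int32)
    for i, (y, x) in enumerate(seeds, start=1):
        markers[y, x] = i
    if markers.max() == 0:
        return ndimage.label(binary)[0].astype(np.int32)
    labels = watershed(-distance, markers=markers, mask=binary)
    return labels.astype(np.int32)


def refine_nuclei_3d(
    nuclei_channel: np.ndarray,
    labels2d: np.ndarray,
    params: SegmentationParams | None = None,
) -> np.ndarray:
    """Fuse the planar instance labels with a 3D threshold-based mask.

    The 3D binary mask from the thresholding chain is intersected with
    the planar label footprint extruded along z; each 3D connected
    region takes the planar label covering the majority of its voxels,
    and final instances below ``min_nucleus_volume`` voxels are removed.
    """
    params = params or SegmentationParams()
    nuclei_channel = np.asarray(nuclei_channel)
    labels2d = np.asarray(labels2d)
    if labels2d.shape != nuclei_channel.shape[1:]:
        raise ValueError("planar labels not aligned to the (y, x) grid")
    mask3d = _threshold_mask_3d(nuclei_channel, params)
    footprint = labels2d > 0
    fused = mask3d & footprint[None, :, :]
    out = np.zeros(nuclei_channel.shape, dtype=np.int32)
    comps, n = ndimage.label(fused)
    for c in range(1, n + 1):
        comp = comps == c
        votes = np.bincount(np.broadcast_to(labels2d, comp.shape)[comp])
        votes[0] = 0
        if votes.max() == 0:
            continue
        out[comp] = int(votes.argmax())
    return filter_small_instances(out, params.min_nucleus_volume)


def segment_cells(
    membrane_channel: np.ndarray,
    nuclei: np.ndarray,
    params: SegmentationParams | None = None,
) -> np.ndarray:
    """Cell instance labels from the cytoplasmic marker channel.

    The binary cell mask (same thresholding chain as nuclei) is
    partitioned among the nuclei by a watershed seeded at the nucleus
    instances; mask regions unreachable from any nucleus (cells without
    nuclei) are excluded. Each cell is union-expanded to contain its
    nucleus, then small cells are removed.
    """
    params = params or SegmentationParams()
    nuclei = np.asarray(nuclei)
    mask = _threshold_mask_3d(membrane_channel, params)
    if nuclei.max() == 0 or not mask.any():
        return np.zeros(np.asarray(membrane_channel).shape, dtype=np.int32)
    # flood the mask from the nuclei; carve along the distance to nuclei
    distance = ndimage.distance_transform_edt(nuclei == 0)
    reach_mask = mask | (nuclei > 0)
    cells = watershed(distance, markers=nuclei.astype(np.int32), mask=reach_mask)
    cells = cells.astype(np.int32)
    # nucleus containment by construction (markers lie inside reach_mask)
    cells[nuclei > 0] = nuclei[nuclei > 0].astype(np.int32)
    cells = filter_small_instances(cells, params.min_cell_volume)
    return cells


def associate(nuclei: np.ndarray, cells: np.ndarray) -> tuple[dict[int, int], list[int]]:
    """Map each nucleus to the cell with maximal voxel overlap.

    Returns ``(nucleus -> cell, flagged)`` where ``flagged`` lists
    nuclei overlapping no cell (excluded downstream).
    """
    nuclei = np.asarray(nuclei)
    cells = np.asarray(cells)
    if nuclei.shape != cells.shape:
        raise ValueError("label volumes must share one grid")
    mapping: dict[int, int] = {}
    flagged: list[int] = []
    nuc_labels = np.unique(nuclei)
    for n in nuc_labels:
        if n == 0:
            continue
        overlap = cells[nuclei == n]
        counts = np.bincount(overlap[overlap > 0])
        if counts.size == 0 or counts.max() == 0:
            flagged.append(int(n))
            log.warning("nucleus %d overlaps no cell; flagged unassigned", n)
        else:
            mapping[int(n)] = int(counts.argmax())
    return mapping, flagged


def segment_timepoint(
    stack: ChannelStack, t: int, params: SegmentationParams | None = None
) -> tuple[np.ndarray, np.ndarray, dict[int, int]]:
    """Full nucleus + cell segmentation of one timepoint.

    Returns ``(nuclei, cells, nucleus_to_cell)``; nuclei without a cell
    are removed from the returned nucleus volume.
    """
    params = params or SegmentationParams()
    mip = max_project(stack, "nuclei", t)
    labels2d = segment_nuclei_planar(mip, params)
    nuclei = refine_nuclei_3d(stack.channel("nuclei", t), labels2d, params)
    cells = segment_cells(stack.channel("membrane", t), nuclei, params)
    mapping, flagged = associate(nuclei, cells)
    for n in flagged:
        nuclei[nuclei == n] = 0
    # drop nuclei whose cell vanished in the size filter
    for n, c in list(mapping.items()):
        if not (cells == c).any():
            nuclei[nuclei == n] = 0
            del mapping[n]
    return nuclei, cells, mapping
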