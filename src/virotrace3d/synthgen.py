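"""Synthetic multi-channel 3D time-lapse generator with exact ground truth.

Emulates the acquisition geometry the pipeline was built for: several
convex adherent cells per field, one thin ellipsoidal nucleus each,
diffraction-limited particle spots at controlled spatial classes,
anisotropic voxel spacing (0.762 um optical sections, 61.8 nm XY
pixels), blur, Poisson + Gaussian read noise, a small rigid drift per
timepoint, and quantized output.

Cells are rendered as randomly oriented ellipses extruded through most
of the z-range (columnar adherent morphology); this guarantees a large
maximum nucleus-to-membrane distance so that the perinuclear shell
(normalized distance <= 0.01 AU) contains whole voxels at the 61.8 nm
pixel pitch. Particles are Gaussian spots; a particle's ground-truth
footprint is the set of voxels its rendered intensity (plus background)
pushes to or above the detection threshold, which is exactly the mask
the seeded watershed recovers at infinite SNR. Placement verifies each
particle's intended class with the same measurement code used by the
pipeline, so simulator and measurer cannot disagree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from . import particles as particle_ops
from .analysis import classify_particle
from .core import DEFAULT_SPACING, ChannelStack, log

CLASS_NAMES = ("inside_nucleus", "nuclear_boundary", "perinuclear", "cytoplasmic")


class PlacementError(RuntimeError):
    """Requested geometry cannot be realized (too many cells, or an
    empty candidate set for a particle class)."""


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic field.

    Defaults follow the acquisition the pipeline targets: 40 optical
    sections, five timepoints at 2 h intervals, voxel spacing
    (0.762, 0.0618, 0.0618) um, 16-bit output on an intensity scale
    where the particle-detection thresholds 300-800 are meaningful
    (spot amplitude 1500 over a background of 100).
    """

    grid_shape: tuple[int, int, int] = (40, 160, 160)  # (z, y, x)
    voxel_spacing: tuple[float, float, float] = DEFAULT_SPACING
    n_timepoints: int = 5
    n_cells: int = 3
    # particles per cell per spatial class
    n_inside: int = 4
    n_boundary: int = 2
    n_perinuclear: int = 1
    n_cytoplasmic: int = 13
    background: float = 100.0
    membrane_amplitude: float = 600.0
    nucleus_amplitude: float = 1200.0
    egfp_amplitudes: tuple[float, ...] = (300.0, 900.0, 1800.0)  # cycled per cell
    particle_amplitude: float = 1500.0
    particle_sigma: tuple[float, float, float] = (0.6, 1.3, 1.3)  # voxels
    detection_threshold: float = 600.0  # used to define ground-truth footprints
    blur_sigma: dict = field(
        default_factory=lambda: {
            "membrane": (0.5, 1.0, 1.0),
            "particles": (0.0, 0.0, 0.0),
            "egfp": (0.5, 1.0, 1.0),
            "nuclei": (0.4, 0.7, 0.7),
        }
    )
    poisson_scale: float = 1.0  # photon gain; noise variance = mean / scale
    read_noise_sd: float = 5.0
    drift: tuple[int, int, int] = (0, 2, 3)  # voxels per timepoint step
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        counts = (self.n_inside, self.n_boundary, self.n_perinuclear, self.n_cytoplasmic)
        if any(c < 0 for c in counts) or self.n_cells < 0 or self.n_timepoints < 1:
            raise ValueError("counts must be non-negative, n_timepoints >= 1")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def class_counts(self) -> dict[str, int]:
        return {
            "inside_nucleus": self.n_inside,
            "nuclear_boundary": self.n_boundary,
            "perinuclear": self.n_perinuclear,
            "cytoplasmic": self.n_cytoplasmic,
        }

    def high_snr(self) -> "SimulationConfig":
        """Low-noise variant for recovery experiments."""
        return replace(self, poisson_scale=4.0, read_noise_sd=3.0)


@dataclass
class GroundTruth:
    """Exact per-timepoint masks, particle table and track identities."""

    cells_by_t: list[np.ndarray]
    nuclei_by_t: list[np.ndarray]
    particles: pd.DataFrame  # per timepoint: ids, centroids, classes, owner
    tracks: pd.DataFrame  # (timepoint, nucleus_label, track_id)


# ------------------------------------------------------------ spot geometry


def footprint_offsets(
    sigma: tuple[float, float, float],
    amplitude: float,
    background: float,
    threshold: float,
) -> np.ndarray:
    """Integer voxel offsets whose rendered spot intensity (over the
    background) reaches the detection threshold."""
    if threshold <= background:
        raise ValueError("threshold must exceed background")
    ratio = amplitude / (threshold - background)
    if ratio < 1:
        return np.empty((0, 3), dtype=int)
    q_max = 2.0 * math.log(ratio)
    radii = [s * math.sqrt(q_max) for s in sigma]
    ranges = [np.arange(-int(math.floor(r)), int(math.floor(r)) + 1) for r in radii]
    grid = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    q = ((grid / np.asarray(sigma)) ** 2).sum(axis=1)
    return grid[q <= q_max]


def _footprint_structure(offsets: np.ndarray) -> np.ndarray:
    """Binary structuring element centred on the spot."""
    r = np.abs(offsets).max(axis=0)
    struct = np.zeros(2 * r + 1, dtype=bool)
    struct[tuple((offsets + r).T)] = True
    return struct


def rasterize_footprint(
    center: np.ndarray, offsets: np.ndarray, shape: tuple[int, int, int]
) -> np.ndarray:
    """Boolean mask of a particle's ground-truth voxel footprint."""
    mask = np.zeros(shape, dtype=bool)
    pts = np.asarray(center, dtype=int) + offsets
    ok = np.all((pts >= 0) & (pts < np.asarray(shape)), axis=1)
    mask[tuple(pts[ok].T)] = True
    return mask


# ------------------------------------------------------------ cell geometry


def _make_cell(
    rng: np.random.Generator,
    grid_shape: tuple[int, int, int],
    margin_lo: np.ndarray,
    margin_hi: np.ndarray,
    existing: list[dict],
    max_tries: int = 200,
) -> dict:
    """Sample one non-overlapping columnar cell with its nucleus geometry."""
    nz, ny, nx = grid_shape
    z0, z1 = max(1, int(0.05 * nz)), nz - 1 - max(1, int(0.06 * nz))
    nuc_zc = int(0.45 * nz)
    nuc_zh = max(1, int(0.05 * nz))
    for attempt in range(max_tries):
        # anneal the radius downwards over retries so crowded layouts
        # still resolve; genuinely infeasible requests exhaust the loop
        shrink = max(0.72, 0.998**attempt)
        r_cell = rng.uniform(0.16, 0.22) * min(ny, nx) * shrink
        ry, rx = r_cell * rng.uniform(0.85, 1.0), r_cell * rng.uniform(0.85, 1.0)
        theta = rng.uniform(0, math.pi)
        cy = rng.uniform(margin_lo[1] + r_cell + 2, ny - 1 - margin_hi[1] - r_cell - 2)
        cx = rng.uniform(margin_lo[2] + r_cell + 2, nx - 1 - margin_hi[2] - r_cell - 2)
        if any(
            math.hypot(cy - e["cy"], cx - e["cx"]) < r_cell + e["r"] + 4
            for e in existing
        ):
            continue
        nry, nrx = 0.45 * ry, 0.45 * rx
        return {
            "cy": cy, "cx": cx, "ry": ry, "rx": rx, "r": r_cell, "theta": theta,
            "z0": z0, "z1": z1, "nry": nry, "nrx": nrx,
            "nz0": nuc_zc - nuc_zh, "nz1": nuc_zc + nuc_zh,
        }
    raise PlacementError(
        f"could not place a non-overlapping cell after {max_tries} tries; "
        f"reduce n_cells or enlarge the grid"
    )


def _rasterize_cell(geom: dict, grid_shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (cell, nucleus) masks for one cell geometry."""
    nz, ny, nx = grid_shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    dy, dx = yy - geom["cy"], xx - geom["cx"]
    c, s = math.cos(geom["theta"]), math.sin(geom["theta"])
    u, v = dy * c + dx * s, -dy * s + dx * c
    ellipse = (u / geom["ry"]) ** 2 + (v / geom["rx"]) ** 2 <= 1.0
    nucleus2d = (u / geom["nry"]) ** 2 + (v / geom["nrx"]) ** 2 <= 1.0
    cell = np.zeros(grid_shape, dtype=bool)
    nucleus = np.zeros(grid_shape, dtype=bool)
    cell[geom["z0"]: geom["z1"] + 1] = ellipse
    nucleus[geom["nz0"]: geom["nz1"] + 1] = nucleus2d
    return cell, nucleus


# -------------------------------------------------------- particle placement


def place_particles(
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    class_counts: dict[str, int],
    spacing: tuple[float, float, float],
    rng: np.random.Generator,
    sigma: tuple[float, float, float] = (0.6, 1.3, 1.3),
    amplitude: float = 1500.0,
    background: float = 100.0,
    threshold: float = 600.0,
    occupied: list[np.ndarray] | None = None,
    min_separation: float = 5.0,
) -> pd.DataFrame:
    """Choose particle centroids realizing the requested spatial classes.

    Candidate voxels per class are derived from the same footprint and
    distance code the measurement module uses, then each placed particle
    is verified: its rasterized footprint, measured at infinite SNR,
    must receive its intended class, otherwise a :class:`PlacementError`
    is raised. ``occupied`` carries already-placed centroids (scaled
    voxel coordinates) for separation checks across cells.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if not (nucleus_mask & ~cell_mask).sum() == 0:
        raise ValueError("nucleus must lie inside the cell")
    offsets = footprint_offsets(sigma, amplitude, background, threshold)
    if len(offsets) == 0:
        raise PlacementError("spot amplitude below detection threshold")
    struct = _footprint_structure(offsets)

    dt = particle_ops.nucleus_distance_field(nucleus_mask, spacing)
    d_max = float(dt[cell_mask].max()) if cell_mask.any() else 0.0
    if d_max <= 0:
        raise PlacementError("degenerate cell: no cytoplasm around the nucleus")
    x_norm_field = dt / d_max

    fully_inside = ndimage.binary_erosion(nucleus_mask, structure=struct)
    touches_nucleus = ndimage.binary_dilation(nucleus_mask, structure=struct)
    touches_outside = ndimage.binary_dilation(~nucleus_mask, structure=struct)
    # keep cytosolic spots a couple of voxels off the plasma membrane so
    # their class and ownership survive sub-voxel segmentation jitter
    interior = ndimage.binary_erosion(cell_mask, structure=np.ones((3, 5, 5), bool))
    clear = ~touches_nucleus & interior
    candidates = {
        "inside_nucleus": fully_inside,
        "nuclear_boundary": touches_nucleus & touches_outside & nucleus_mask,
        "perinuclear": clear & (x_norm_field > 0) & (x_norm_field <= 0.01),
        "cytoplasmic": clear & (x_norm_field > 0.01),
    }

    placed: list[np.ndarray] = list(occupied) if occupied else []
    zscale = np.array([sigma[1] / sigma[0], 1.0, 1.0])  # z steps count more

    rows = []
    shape = cell_mask.shape
    for cls in CLASS_NAMES:
        want = class_counts.get(cls, 0)
        pool = np.argwhere(candidates[cls])
        if want > 0 and len(pool) == 0:
            raise PlacementError(f"no candidate voxels for class {cls!r}")
        order = rng.permutation(len(pool))
        got = 0
        for idx in order:
            if got == want:
                break
            p = pool[idx]
            scaled = p * zscale
            if any(np.linalg.norm(scaled - q) < min_separation for q in placed):
                continue
            fp = rasterize_footprint(p, offsets, shape)
            nr = particle_ops.compute_nuclear_ratio(fp, nucleus_mask)
            centroid = np.mean(np.argwhere(fp), axis=0)
            x_raw, x_norm = particle_ops.compute_distances(
                centroid, nr, nucleus_mask, cell_mask, spacing, d_max=d_max
            )
            if classify_particle(nr, x_norm) != cls:
                continue
            placed.append(scaled)
            got += 1
            rows.append(
                {
                    "z": int(p[0]), "y": int(p[1]), "x": int(p[2]),
                    "true_class": cls, "nuclear_ratio_true": nr,
                    "x_norm_true": x_norm, "radius_um": sigma[1] * spacing[1],
                    "amplitude": amplitude,
                }
            )
        if got < want:
            raise PlacementError(
                f"placed only {got}/{want} particles of class {cls!r}; "
                f"geometry too crowded"
            )
    if occupied is not None:
        occupied[:] = placed
    return pd.DataFrame(
        rows,
        columns=[
            "z", "y", "x", "true_class", "nuclear_ratio_true",
            "x_norm_true", "radius_um", "amplitude",
        ],
    )


# ----------------------------------------------------------- optics & noise


def apply_optics_and_noise(
    geometry: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Blur per channel, add Poisson + Gaussian read noise, quantize.

    ``geometry`` is a (t, c, z, y, x) noiseless stack on the final
    intensity scale. Poisson noise has variance mean/``poisson_scale``;
    a scale of 0 disables it. Output is clipped to the bit depth and
    rounded to integers.
    """
    roles = {"membrane": 0, "particles": 1, "egfp": 2, "nuclei": 3}
    out = np.empty_like(geometry, dtype=float)
    for role, c in roles.items():
        sigma = config.blur_sigma.get(role, (0, 0, 0))
        for t in range(geometry.shape[0]):
            vol = geometry[t, c].astype(float)
            if any(s > 0 for s in sigma):
                vol = ndimage.gaussian_filter(vol, sigma=sigma)
            if config.poisson_scale > 0:
                vol = rng.poisson(np.clip(vol, 0, None) * config.poisson_scale) / (
                    config.poisson_scale
                )
            if config.read_noise_sd > 0:
                vol = vol + rng.normal(0.0, config.read_noise_sd, vol.shape)
            out[t, c] = vol
    vmax = 2**config.bit_depth - 1
    out = np.clip(np.round(out), 0, vmax)
    return out.astype(np.uint8 if config.bit_depth == 8 else np.uint16)


# -------------------------------------------------------------- time lapse


def _shift_mask(mask: np.ndarray, offset: tuple[int, int, int]) -> np.ndarray:
    out = np.zeros_like(mask)
    src = []
    dst = []
    for ax, off in enumerate(offset):
        n = mask.shape[ax]
        if abs(off) >= n:
            return out
        if off >= 0:
            src.append(slice(0, n - off))
            dst.append(slice(off, n))
        else:
            src.append(slice(-off, n))
            dst.append(slice(0, n + off))
    out[tuple(dst)] = mask[tuple(src)]
    return out


def _render_spots(
    shape: tuple[int, int, int],
    table: pd.DataFrame,
    sigma: tuple[float, float, float],
) -> np.ndarray:
    vol = np.zeros(shape, dtype=float)
    cut = [max(1, int(math.ceil(4 * s))) for s in sigma]
    for row in table.itertuples():
        center = np.array([row.z, row.y, row.x], dtype=float)
        lo = np.maximum(np.floor(center - cut).astype(int), 0)
        hi = np.minimum(np.ceil(center + cut).astype(int) + 1, shape)
        zz, yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        q = (
            ((zz - center[0]) / sigma[0]) ** 2
            + ((yy - center[1]) / sigma[1]) ** 2
            + ((xx - center[2]) / sigma[2]) ** 2
        )
        vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += row.amplitude * np.exp(-q / 2.0)
    return vol


def generate_timelapse(config: SimulationConfig) -> tuple[ChannelStack, GroundTruth]:
    """Render the full synthetic time-lapse with ground truth.

    The scene geometry is built once, then rigidly translated by the
    cumulative drift at every timepoint before optics and noise are
    applied, so the pre-noise geometry is identical across timepoints up
    to the configured drift.
    """
    rng = np.random.default_rng(config.seed)
    shape = config.grid_shape
    total_drift = np.abs(np.asarray(config.drift)) * (config.n_timepoints - 1)
    drift_arr = np.asarray(config.drift)
    margin_lo = np.where(drift_arr < 0, total_drift, 0)
    margin_hi = np.where(drift_arr > 0, total_drift, 0)

    geoms: list[dict] = []
    for _ in range(config.n_cells):
        geoms.append(_make_cell(rng, shape, margin_lo, margin_hi, geoms))

    cells0 = np.zeros(shape, dtype=np.int32)
    nuclei0 = np.zeros(shape, dtype=np.int32)
    cell_masks = []
    nucleus_masks = []
    for i, g in enumerate(geoms, start=1):
        cmask, nmask = _rasterize_cell(g, shape)
        cmask &= cells0 == 0  # first-placed cell wins contested voxels
        nmask &= cmask
        cells0[cmask] = i
        nuclei0[nmask] = i
        cell_masks.append(cmask)
        nucleus_masks.append(nmask)

    occupied: list[np.ndarray] = []
    tables = []
    for i, (cmask, nmask) in enumerate(zip(cell_masks, nucleus_masks), start=1):
        tbl = place_particles(
            cmask,
            nmask,
            config.class_counts,
            config.voxel_spacing,
            rng,
            sigma=config.particle_sigma,
            amplitude=config.particle_amplitude,
            background=config.background,
            threshold=config.detection_threshold,
            occupied=occupied,
        )
        tbl["cell_label"] = i
        tables.append(tbl)
    base_particles = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(
            columns=[
                "z", "y", "x", "true_class", "nuclear_ratio_true", "x_norm_true",
                "radius_um", "amplitude", "cell_label",
            ]
        )
    )
    base_particles.insert(0, "particle_id", np.arange(1, len(base_particles) + 1))

    # per-cell eGFP level, cycled deterministically
    egfp_level = {
        i + 1: config.egfp_amplitudes[i % len(config.egfp_amplitudes)]
        for i in range(config.n_cells)
    }

    geometry = np.zeros((config.n_timepoints, 4, *shape), dtype=float)
    cells_by_t, nuclei_by_t = [], []
    particle_rows = []
    track_rows = []
    for t in range(config.n_timepoints):
        off = tuple(int(v) for v in drift_arr * t)
        cells_t = _shift_mask(cells0, off)
        nuclei_t = _shift_mask(nuclei0, off)
        cells_by_t.append(cells_t)
        nuclei_by_t.append(nuclei_t)
        for lbl in range(1, config.n_cells + 1):
            track_rows.append({"timepoint": t, "nucleus_label": lbl, "track_id": lbl - 1})

        geometry[t, 0] = config.background + config.membrane_amplitude * (cells_t > 0)
        egfp = np.full(shape, config.background)
        for lbl, amp in egfp_level.items():
            egfp[cells_t == lbl] += amp
        geometry[t, 2] = egfp
        geometry[t, 3] = config.background + config.nucleus_amplitude * (nuclei_t > 0)

        tbl = base_particles.copy()
        if len(tbl):
            tbl["timepoint"] = t
            tbl[["z", "y", "x"]] = tbl[["z", "y", "x"]].to_numpy() + np.asarray(off)
            particle_rows.append(tbl)
            geometry[t, 1] = config.background + _render_spots(
                shape, tbl, config.particle_sigma
            )
        else:
            geometry[t, 1] = config.background

    stack = ChannelStack(
        data=apply_optics_and_noise(geometry, config, rng),
        spacing=config.voxel_spacing,
    )
    particles_df = (
        pd.concat(particle_rows, ignore_index=True)
        if particle_rows
        else base_particles.assign(timepoint=pd.Series(dtype=int))
    )
    truth = GroundTruth(
        cells_by_t=cells_by_t,
        nuclei_by_t=nuclei_by_t,
        particles=particles_df,
        tracks=pd.DataFrame(track_rows, columns=["timepoint", "nucleus_label", "track_id"]),
    )
    log.info(
        "generated %d-timepoint field: %d cells, %d particles per timepoint",
        config.n_timepoints, config.n_cells, len(base_particles),
    )
    return stack, truth
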