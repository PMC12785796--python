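"""End-to-end orchestration: segment -> track -> detect -> measure -> classify.

``run_pipeline`` consumes a :class:`~virotrace3d.core.ChannelStack` and
returns tidy tables ready for the analysis module; the CLI and the
acceptance experiments are thin wrappers over it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, particles as particle_ops, segmentation, tracking
from .core import DEFAULT_CHANNEL_ROLES, DEFAULT_SPACING, ChannelStack, log


@dataclass
class PipelineConfig:
    """Everything the pipeline needs for one run."""

    channel_roles: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_ROLES))
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    segmentation: segmentation.SegmentationParams = field(
        default_factory=segmentation.SegmentationParams
    )
    tracking: tracking.TrackParams = field(default_factory=tracking.TrackParams)
    particles: particle_ops.ParticleParams = field(
        default_factory=particle_ops.ParticleParams
    )
    condition: str = "default"
    roi: str = "roi0"
    timepoint_hours: tuple[int, ...] = (4, 6, 8, 10, 12)
    nuclear_counts_boundary_inclusive: bool = True
    include_zero_particle_cells_in_fractions: bool = False
    out_dir: str = "results"
    seed: int = 0

    @classmethod
    def desk_scale(cls, **overrides) -> "PipelineConfig":
        """Profile for small synthetic fields (see SegmentationParams)."""
        cfg = cls(segmentation=segmentation.SegmentationParams.desk_scale())
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for section, target in (
            ("segmentation", segmentation.SegmentationParams),
            ("tracking", tracking.TrackParams),
            ("particles", particle_ops.ParticleParams),
        ):
            if section in raw:
                setattr(cfg, section, target(**raw.pop(section)))
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if key in ("spacing", "timepoint_hours"):
                value = tuple(value)
            setattr(cfg, key, value)
        return cfg


def _echo_params(stack: ChannelStack, config: PipelineConfig) -> None:
    digest = hashlib.sha256(np.ascontiguousarray(stack.data).tobytes()).hexdigest()[:16]
    log.info("input stack %s sha256[:16]=%s", stack.data.shape, digest)
    log.info("segmentation=%s", config.segmentation)
    log.info("tracking=%s particles=%s", config.tracking, config.particles)


def run_pipeline(
    stack: ChannelStack, config: PipelineConfig | None = None
) -> dict[str, object]:
    """Run the full quantification pipeline on one stack.

    Returns a dict with per-timepoint label volumes (``nuclei``,
    ``cells`` — cells relabeled by nucleus track), the nucleus track
    table, the classified per-particle table and the per-cell
    per-timepoint aggregate table.
    """
    config = config or PipelineConfig()
    _echo_params(stack, config)

    nuclei_by_t, cells_by_t, maps = [], [], []
    for t in range(stack.n_timepoints):
        nuclei, cells, mapping = segmentation.segment_timepoint(
            stack, t, config.segmentation
        )
        nuclei_by_t.append(nuclei)
        cells_by_t.append(cells)
        maps.append(mapping)
        log.info("t=%d: %d nuclei / %d cells", t, len(mapping), len(set(mapping.values())))

    frames = tracking.centroid_frames(nuclei_by_t)
    tracks = tracking.link_nuclei(frames, config.tracking)
    cells_tracked, cell_table = tracking.relabel_cells_by_track(
        cells_by_t, maps, tracks
    )

    hours = list(config.timepoint_hours)
    particle_tables = []
    cell_rows = []
    for t in range(stack.n_timepoints):
        vol = stack.channel("particles", t)
        centroids = particle_ops.detect_centroids(vol, config.particles)
        labels = particle_ops.segment_particles(
            vol, centroids, config.particles.threshold
        )
        # measure against track-relabeled cells; nuclei carry their own
        # per-timepoint labels, so build the cell->nucleus map in track space
        sub = cell_table[cell_table["timepoint"] == t]
        track_label_of_cell = {}  # tracked cell label -> nucleus label
        for row in sub.itertuples():
            track_label_of_cell[row.track_id + 1] = row.nucleus_label
        measured = particle_ops.measure_particles(
            vol,
            labels,
            cells_tracked[t],
            nuclei_by_t[t],
            track_label_of_cell,
            stack.spacing,
            timepoint=t,
        )
        measured = analysis.add_spatial_classes(measured)
        measured["track_id"] = measured["cell_label"] - 1
        particle_tables.append(measured)

        egfp = stack.channel("egfp", t)
        for row in sub.itertuples():
            cmask = cells_tracked[t] == row.track_id + 1
            nmask = nuclei_by_t[t] == row.nucleus_label
            cell_rows.append(
                {
                    "timepoint": t,
                    "hours": hours[t] if t < len(hours) else t,
                    "track_id": row.track_id,
                    "cell_label": row.track_id + 1,
                    "cell_volume_vox": int(cmask.sum()),
                    "nucleus_volume_vox": int(nmask.sum()),
                    "mean_egfp": float(egfp[cmask].mean()) if cmask.any() else np.nan,
                }
            )

    particles_df = pd.concat(particle_tables, ignore_index=True)
    cell_info = pd.DataFrame(
        cell_rows,
        columns=[
            "timepoint", "hours", "track_id", "cell_label",
            "cell_volume_vox", "nucleus_volume_vox", "mean_egfp",
        ],
    )
    cells_df = analysis.aggregate_cells(
        particles_df,
        cell_info,
        nuclear_counts_boundary_inclusive=config.nuclear_counts_boundary_inclusive,
    )
    for df in (particles_df, cells_df):
        df["condition"] = config.condition
        df["roi"] = config.roi
    return {
        "nuclei_by_t": nuclei_by_t,
        "cells_by_t": cells_tracked,
        "tracks": tracks,
        "particles": particles_df,
        "cells": cells_df,
    }
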