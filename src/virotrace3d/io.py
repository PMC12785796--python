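"""File formats, dataset merging, curation and QC rendering.

Stacks travel as OME-TIFF with TCZYX axes and physical pixel sizes in
micrometres; label masks as plain TIFF; tables as UTF-8 comma-separated
CSV with "." decimals. Coordinates in tables are 0-based voxel indices
in (z, y, x) order.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import tifffile

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .core import DEFAULT_CHANNEL_ROLES, ChannelStack, log  # noqa: E402

TIMEPOINT_HOURS = (4, 6, 8, 10, 12)

CURATION_REASONS = ("mitosis", "apoptosis", "segmentation_error", "other")

MEASUREMENT_KEY = ["condition", "roi", "timepoint", "cell_label"]


# ------------------------------------------------------------------ stacks


def write_stack(path: str | Path, stack: ChannelStack) -> None:
    """Write a ChannelStack as OME-TIFF (TCZYX) with spacing metadata."""
    sz, sy, sx = stack.spacing
    tifffile.imwrite(
        str(path),
        stack.data,
        ome=True,
        metadata={
            "axes": "TCZYX",
            "PhysicalSizeZ": sz,
            "PhysicalSizeY": sy,
            "PhysicalSizeX": sx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
        },
    )


def _spacing_from_ome(xml_text: str) -> tuple[float, float, float] | None:
    try:
        root = ET.fromstring(xml_text)
        for pixels in root.iter():
            if pixels.tag.endswith("Pixels"):
                z = pixels.get("PhysicalSizeZ")
                y = pixels.get("PhysicalSizeY")
                x = pixels.get("PhysicalSizeX")
                if z and y and x:
                    return float(z), float(y), float(x)
    except ET.ParseError:
        return None
    return None


def read_stack(
    path: str | Path,
    spacing_override: tuple[float, float, float] | None = None,
    channel_roles: dict[str, int] | None = None,
) -> ChannelStack:
    """Read an OME-TIFF (or multi-page TIFF) into a ChannelStack.

    Axes must resolve to a subset of TCZYX; missing leading axes are
    re-inserted with length 1. Spacing comes from OME metadata unless
    overridden; absence of both is an error.
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        axes = series.axes.upper().replace("S", "C")
        data = series.asarray()
        ome_xml = tif.ome_metadata
    if any(ax not in "TCZYX" for ax in axes):
        # plain multi-page TIFFs carry no reliable axis tags ('Q'/'I'
        # placeholders); fall back to TCZYX order, right-aligned
        if data.ndim > 5:
            raise ValueError(f"unresolvable axes in {path.name} (axes={axes})")
        axes = "TCZYX"[5 - data.ndim :]
    if len(set(axes)) != len(axes):
        raise ValueError(f"ambiguous axes in {path.name} (axes={axes})")
    for i, ax in enumerate("TCZYX"):
        if ax not in axes:
            axes = ax + axes
            data = np.expand_dims(data, 0)
    order = [axes.index(ax) for ax in "TCZYX"]
    data = np.transpose(data, order)

    spacing = _spacing_from_ome(ome_xml) if ome_xml else None
    if spacing_override is not None:
        if spacing is None:
            log.warning("%s lacks spacing metadata; using configured override", path.name)
        spacing = spacing_override
    if spacing is None:
        raise ValueError(f"{path.name}: no spacing metadata and no override given")

    roles = channel_roles or dict(DEFAULT_CHANNEL_ROLES)
    n_channels = data.shape[1]
    if max(roles.values()) >= n_channels:
        raise ValueError(
            f"{path.name}: {n_channels} channels cannot satisfy role map {roles}"
        )
    return ChannelStack(data=data, spacing=spacing, channel_roles=roles)


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    tifffile.imwrite(
        str(path), np.asarray(labels).astype(np.int32), photometric="minisblack"
    )


def read_labels(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


# ----------------------------------------------------------------- merging


def parse_timepoint(token) -> int:
    """Normalize timepoint tokens ('4h', '4 h', 4, '4') to integer hours."""
    if isinstance(token, (int, np.integer)):
        return int(token)
    text = str(token).strip().lower().removesuffix("h").strip()
    try:
        return int(float(text))
    except ValueError:
        raise ValueError(f"cannot parse timepoint token {token!r}") from None


def merge_measurements(paths: list[str | Path]) -> pd.DataFrame:
    """Combine per-ROI per-timepoint measurement CSVs into one dataset.

    All files must share the measurement schema; duplicate
    (condition, roi, timepoint, cell_label) keys are an error. Rows are
    canonically sorted so merging is order-invariant.
    """
    frames = []
    reference_cols = None
    for p in paths:
        df = pd.read_csv(p)
        missing = [c for c in MEASUREMENT_KEY if c not in df.columns]
        if missing:
            raise ValueError(f"{Path(p).name}: missing columns {missing}")
        if reference_cols is None:
            reference_cols = list(df.columns)
        elif set(df.columns) != set(reference_cols):
            diff = set(reference_cols).symmetric_difference(df.columns)
            raise ValueError(f"{Path(p).name}: schema mismatch on columns {sorted(diff)}")
        frames.append(df)
    if not frames:
        raise ValueError("no measurement files given")
    merged = pd.concat(frames, ignore_index=True)
    merged["timepoint"] = merged["timepoint"].map(parse_timepoint)
    dupes = merged.duplicated(subset=MEASUREMENT_KEY)
    if dupes.any():
        keys = merged.loc[dupes, MEASUREMENT_KEY].to_dict("records")[:5]
        raise ValueError(f"duplicate measurement keys, e.g. {keys}")
    return merged.sort_values(MEASUREMENT_KEY, kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------- curation


def apply_curation(
    dataset: pd.DataFrame,
    curation: pd.DataFrame,
    particle_dataset: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.DataFrame]:
    """Remove excluded cells (all timepoints) and their particles.

    ``curation`` has columns ``condition, roi, cell_track_id, reason``.
    Unknown keys warn; the returned audit log counts removed cell rows
    by reason. Applying the same list twice is a no-op the second time.
    """
    for col in ("condition", "roi", "cell_track_id", "reason"):
        if col not in curation.columns:
            raise ValueError(f"curation list missing column {col!r}")
    bad = set(curation["reason"]) - set(CURATION_REASONS)
    if bad:
        raise ValueError(f"unknown curation reasons {sorted(bad)}")

    track_col = "track_id" if "track_id" in dataset.columns else "cell_label"
    out = dataset
    particles_out = particle_dataset
    audit_rows = []
    for row in curation.itertuples():
        mask = (
            (out["condition"] == row.condition)
            & (out["roi"] == row.roi)
            & (out[track_col] == row.cell_track_id)
        )
        n = int(mask.sum())
        if n == 0:
            log.warning(
                "curation key (%s, %s, %s) matches no cells",
                row.condition, row.roi, row.cell_track_id,
            )
        out = out[~mask]
        n_particles = 0
        if particles_out is not None and track_col in particles_out.columns:
            pmask = (
                (particles_out["condition"] == row.condition)
                & (particles_out["roi"] == row.roi)
                & (particles_out[track_col] == row.cell_track_id)
            )
            n_particles = int(pmask.sum())
            particles_out = particles_out[~pmask]
        audit_rows.append(
            {
                "condition": row.condition,
                "roi": row.roi,
                "cell_track_id": row.cell_track_id,
                "reason": row.reason,
                "cell_rows_removed": n,
                "particle_rows_removed": n_particles,
            }
        )
    audit = pd.DataFrame(
        audit_rows,
        columns=[
            "condition", "roi", "cell_track_id", "reason",
            "cell_rows_removed", "particle_rows_removed",
        ],
    )
    return out.reset_index(drop=True), (
        particles_out.reset_index(drop=True) if particles_out is not None else None
    ), audit


# -------------------------------------------------------------- QC overlays

_CLASS_COLORS = {
    "inside_nucleus": "tab:red",
    "nuclear_boundary": "tab:orange",
    "perinuclear": "tab:cyan",
    "cytoplasmic": "tab:green",
}


def render_qc_overlays(
    stack: ChannelStack,
    nuclei_by_t: list[np.ndarray] | None,
    cells_by_t: list[np.ndarray] | None,
    particles: pd.DataFrame | None,
    out_dir: str | Path,
) -> list[Path]:
    """Per-timepoint MIP with cell/nucleus contours, class-coloured
    particle markers and track-id labels. Returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in range(stack.n_timepoints):
        fig, ax = plt.subplots(figsize=(6, 6))
        mip = stack.channel("nuclei", t).max(axis=0)
        ax.imshow(mip, cmap="gray")
        for vols, color in ((cells_by_t, "yellow"), (nuclei_by_t, "deepskyblue")):
            if vols is None or t >= len(vols):
                continue
            proj = np.asarray(vols[t]).max(axis=0)
            for lbl in np.unique(proj):
                if lbl == 0:
                    continue
                ax.contour(proj == lbl, levels=[0.5], colors=color, linewidths=0.8)
                cy, cx = np.mean(np.argwhere(proj == lbl), axis=0)
                if color == "yellow":
                    ax.text(cx, cy, str(int(lbl)), color="yellow", fontsize=8)
        if particles is not None and len(particles):
            sub = particles[particles["timepoint"] == t]
            cls_col = "spatial_class" if "spatial_class" in sub.columns else None
            for row in sub.itertuples():
                color = _CLASS_COLORS.get(getattr(row, cls_col), "white") if cls_col else "white"
                ax.plot(row.x, row.y, "o", mfc="none", mec=color, ms=5, mew=0.8)
        ax.set_axis_off()
        path = out_dir / f"qc_t{t:02d}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
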