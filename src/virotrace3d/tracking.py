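"""Nucleus tracking across timepoints with gap closing.

Frame-to-frame linking is solved as an optimal (minimum total
displacement) assignment between active tracks and current detections,
with links forbidden beyond the search range. A track missing for up to
``memory`` consecutive timepoints may be re-linked; beyond that a new
identity is issued. Cells inherit the track id of their nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core import log

_FORBIDDEN = 1e12


@dataclass
class TrackParams:
    """``search_range`` is the maximum XY centroid displacement (pixels)
    between linked consecutive observations; ``memory`` the number of
    consecutive missed timepoints a track survives."""

    search_range: float = 400.0
    memory: int = 3

    def __post_init__(self) -> None:
        if self.search_range <= 0:
            raise ValueError("search_range must be positive")
        if self.memory < 0:
            raise ValueError("memory must be >= 0")


def link_nuclei(
    frames: list[pd.DataFrame], params: TrackParams | None = None
) -> pd.DataFrame:
    """Link per-timepoint nucleus centroids into tracks.

    ``frames[t]`` holds columns ``label, y, x`` (projected 2D centroids)
    for timepoint ``t``; empty frames are allowed. Returns the track
    table with columns ``timepoint, label, track_id, y, x``.
    """
    params = params or TrackParams()
    if len(frames) == 0:
        raise ValueError("need at least one timepoint")

    rows: list[dict] = []
    active: list[dict] = []  # {"id", "pos", "last_t"}
    next_id = 0
    for t, frame in enumerate(frames):
        frame = frame.sort_values("label") if len(frame) else frame
        dets = frame[["y", "x"]].to_numpy(dtype=float) if len(frame) else np.empty((0, 2))
        labels = frame["label"].to_numpy() if len(frame) else np.empty(0, dtype=int)

        candidates = [tr for tr in active if t - tr["last_t"] - 1 <= params.memory]
        assigned_det = {}
        if candidates and len(dets):
            cost = np.full((len(candidates), len(dets)), _FORBIDDEN)
            for i, tr in enumerate(candidates):
                d = np.hypot(*(dets - tr["pos"]).T)
                ok = d <= params.search_range
                cost[i, ok] = d[ok]
            rows_idx, cols_idx = linear_sum_assignment(cost)
            for i, j in zip(rows_idx, cols_idx):
                if cost[i, j] < _FORBIDDEN:
                    assigned_det[j] = candidates[i]

        for j in range(len(dets)):
            if j in assigned_det:
                tr = assigned_det[j]
            else:
                tr = {"id": next_id, "pos": None, "last_t": None}
                next_id += 1
                active.append(tr)
            tr["pos"] = dets[j]
            tr["last_t"] = t
            rows.append(
                {
                    "timepoint": t,
                    "label": int(labels[j]),
                    "track_id": tr["id"],
                    "y": dets[j][0],
                    "x": dets[j][1],
                }
            )
        active = [tr for tr in active if t - tr["last_t"] <= params.memory]
    return pd.DataFrame(rows, columns=["timepoint", "label", "track_id", "y", "x"])


def centroid_frames(nuclei_by_t: list[np.ndarray]) -> list[pd.DataFrame]:
    """Projected (y, x) centroids per nucleus label for each timepoint."""
    frames = []
    for nuclei in nuclei_by_t:
        nuclei = np.asarray(nuclei)
        labels = [int(l) for l in np.unique(nuclei) if l != 0]
        recs = []
        for l in labels:
            zyx = np.mean(np.argwhere(nuclei == l), axis=0)
            recs.append({"label": l, "y": zyx[1], "x": zyx[2]})
        frames.append(pd.DataFrame(recs, columns=["label", "y", "x"]))
    return frames


def relabel_cells_by_track(
    cells_by_t: list[np.ndarray],
    nucleus_to_cell_by_t: list[dict[int, int]],
    tracks: pd.DataFrame,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Carry each nucleus's track id onto its cell at every timepoint.

    Returns relabeled cell volumes (labels are ``track_id + 1`` so 0
    stays background) and a longitudinal table with columns
    ``timepoint, track_id, nucleus_label, cell_label``. Cells claimed by
    two nuclei with different tracks are flagged multi-nucleated and
    excluded with a warning; untracked nuclei drop their cell at that
    timepoint.
    """
    relabeled = []
    rows = []
    for t, (cells, mapping) in enumerate(zip(cells_by_t, nucleus_to_cell_by_t)):
        cells = np.asarray(cells)
        sub = tracks[tracks["timepoint"] == t]
        track_of_nucleus = dict(zip(sub["label"], sub["track_id"]))
        cell_claims: dict[int, set[int]] = {}
        for n, c in mapping.items():
            if n in track_of_nucleus:
                cell_claims.setdefault(c, set()).add(int(track_of_nucleus[n]))
        out = np.zeros_like(cells, dtype=np.int32)
        for c, claim in sorted(cell_claims.items()):
            if len(claim) > 1:
                log.warning(
                    "timepoint %d: cell %d claimed by tracks %s; "
                    "flagged multi-nucleated and excluded",
                    t, c, sorted(claim),
                )
                continue
            track = claim.pop()
            out[cells == c] = track + 1
            nucleus = next(n for n, cc in mapping.items() if cc == c)
            rows.append(
                {
                    "timepoint": t,
                    "track_id": track,
                    "nucleus_label": nucleus,
                    "cell_label": c,
                }
            )
        relabeled.append(out)
    table = pd.DataFrame(
        rows, columns=["timepoint", "track_id", "nucleus_label", "cell_label"]
    )
    return relabeled, table
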