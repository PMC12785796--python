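"""Shared containers and conventions.

Coordinate convention: all voxel coordinates are 0-based ``(z, y, x)``
indices; physical coordinates are micrometres, obtained by multiplying
each axis index by the voxel spacing for that axis. Image grids are
indexed ``(t, c, z, y, x)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger("virotrace3d")

#: channel order used throughout: plasma-membrane/cytoplasmic marker,
#: labeled viral particles, transgene eGFP, nuclear DNA marker.
DEFAULT_CHANNEL_ROLES = {"membrane": 0, "particles": 1, "egfp": 2, "nuclei": 3}

#: acquisition geometry: 762 nm optical sections, 61.8 nm XY pixels.
DEFAULT_SPACING = (0.762, 0.0618, 0.0618)

#: time course in hours post vector-entry synchronization.
DEFAULT_TIMEPOINT_HOURS = (4, 6, 8, 10, 12)


def configure_logging(level: str = "INFO") -> None:
    """Attach a plain stderr handler to the package logger once."""
    if not log.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        log.addHandler(handler)
    log.setLevel(level.upper())


@dataclass
class ChannelStack:
    """Multi-channel 3D time-lapse intensity grid.

    Parameters
    ----------
    data:
        Array indexed ``(t, c, z, y, x)``, non-negative intensities.
    spacing:
        Physical voxel size per spatial axis ``(z, y, x)`` in micrometres.
    channel_roles:
        Map from role name (``membrane``, ``particles``, ``egfp``,
        ``nuclei``) to channel index.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    channel_roles: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_ROLES)
    )

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(
                f"ChannelStack data must be (t, c, z, y, x); got {self.data.ndim} axes"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        n_channels = self.data.shape[1]
        bad = {r: c for r, c in self.channel_roles.items() if not 0 <= c < n_channels}
        if bad:
            raise ValueError(
                f"channel roles {bad} out of range for {n_channels}-channel stack"
            )
        if self.data.size and self.data.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[2:])

    def channel(self, role: str, t: int) -> np.ndarray:
        """Return the 3D ``(z, y, x)`` volume for one role at one timepoint."""
        if role not in self.channel_roles:
            raise KeyError(
                f"unknown channel role {role!r}; have {sorted(self.channel_roles)}"
            )
        if not 0 <= t < self.n_timepoints:
            raise IndexError(f"timepoint {t} out of range [0, {self.n_timepoints})")
        return self.data[t, self.channel_roles[role]]
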