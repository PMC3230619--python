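"""Depth x time tracer profiles — the common currency of the package.

A :class:`ProfileSeries` holds the matrix of tracer counts per sediment
layer (rows, interface first) over time (columns), plus the physical
scales needed to convert layers to millimetres and columns to minutes.
Both observed (image-derived) and simulated profiles use this container.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = ["ProfileSeries"]


@dataclass
class ProfileSeries:
    counts: np.ndarray
    dt_min: float = 5.0
    layer_height_mm: float = 0.073

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ConfigurationError(
                f"profile counts must be 2-D (layers x times), got shape {self.counts.shape}"
            )
        if self.counts.size and np.any(self.counts < 0):
            raise ConfigurationError("profile counts must be non-negative")

    @property
    def n_layers(self) -> int:
        return self.counts.shape[0]

    @property
    def n_times(self) -> int:
        return self.counts.shape[1]

    def times_min(self) -> np.ndarray:
        """Elapsed time of each column, in minutes."""
        return np.arange(self.n_times) * self.dt_min

    def depths_mm(self) -> np.ndarray:
        """Depth of each layer's lower boundary, in mm below the interface."""
        return (np.arange(self.n_layers) + 1) * self.layer_height_mm

    def total_per_time(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def penetration_depth_mm(self, time_index: int = -1) -> float:
        """Depth of the deepest layer holding any tracer at a time point.

        Returns 0.0 if the column holds no tracer at all.
        """
        column = self.counts[:, time_index]
        nz = np.nonzero(column)[0]
        if nz.size == 0:
            return 0.0
        return float((nz[-1] + 1) * self.layer_height_mm)

    def mean_depth_layers(self, time_index: int = -1) -> float:
        """Tracer-weighted mean depth (layer units, layer centres)."""
        column = self.counts[:, time_index].astype(float)
        total = column.sum()
        if total == 0:
            return float("nan")
        return float(np.arange(self.n_layers) @ column / total)

    def depth_variance_layers(self, time_index: int = -1) -> float:
        """Tracer-weighted depth variance (layers^2) at a time point."""
        column = self.counts[:, time_index].astype(float)
        total = column.sum()
        if total == 0:
            return float("nan")
        idx = np.arange(self.n_layers)
        mu = idx @ column / total
        return float(((idx - mu) ** 2) @ column / total)
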