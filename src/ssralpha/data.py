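"""Core in-memory containers: epoched multichannel EEG and sensor montages.

Conventions used throughout the package:

* epoched data are ``(n_trials, n_channels, n_samples)`` float arrays;
* sensor positions live on the unit sphere with ``+x`` pointing to the
  subject's right, ``+y`` anterior and ``+z`` up, so the left/right
  hemisphere split is the sign of the x coordinate;
* condition labels are free strings; the attention experiment uses
  ``"attend-left"`` and ``"attend-right"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

ATTEND_LEFT = "attend-left"
ATTEND_RIGHT = "attend-right"


@dataclass
class Montage:
    """Sensor positions on the unit sphere plus a neighbourhood graph.

    Parameters
    ----------
    positions : (n_channels, 3) ndarray
        Unit-norm electrode positions.
    adjacency : (n_channels, n_channels) bool ndarray
        Symmetric neighbourhood indicator with a zero diagonal; used for
        spatial clustering.
    names : list of str
        Channel identifiers.
    """

    positions: np.ndarray
    adjacency: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        n = self.positions.shape[0]
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n_channels, 3)")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("positions must lie on the unit sphere")
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape must match positions")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency)):
            raise ValueError("adjacency diagonal must be zero")
        if not self.names:
            self.names = [f"ch{i:02d}" for i in range(n)]
        if len(self.names) != n:
            raise ValueError("names length must match positions")

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    @property
    def left_channels(self) -> np.ndarray:
        """Indices of left-hemisphere sensors (x < 0)."""
        return np.flatnonzero(self.positions[:, 0] < 0)

    @property
    def right_channels(self) -> np.ndarray:
        return np.flatnonzero(self.positions[:, 0] > 0)

    def neighbor_lists(self) -> list[np.ndarray]:
        return [np.flatnonzero(row) for row in self.adjacency]


@dataclass
class Epochs:
    """Epoched multichannel time series with per-trial condition labels."""

    data: np.ndarray
    srate: float
    condition: np.ndarray
    channel_names: list[str]
    t0: float = 0.0
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.condition = np.asarray(self.condition)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if np.isnan(self.data).any():
            raise ValueError("data contains NaNs")
        if self.condition.shape[0] != self.data.shape[0]:
            raise ValueError("one condition label per trial required")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must match channel axis")
        if self.data.shape[0] < 1:
            raise ValueError("at least one trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.srate

    def select(self, condition: str) -> "Epochs":
        """Return the sub-epochs belonging to one condition."""
        mask = self.condition == condition
        if not mask.any():
            raise ValueError(f"no trials with condition {condition!r}")
        return replace(self, data=self.data[mask], condition=self.condition[mask])

    def copy_with(self, data: np.ndarray, units: str | None = None) -> "Epochs":
        return replace(self, data=data, units=units or self.units)
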