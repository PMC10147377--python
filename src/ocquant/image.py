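"""In-memory containers for multi-channel rasters and instance masks.

A :class:`ChannelImage` is channel-first (``C, H, W`` for sections,
``C, Z, Y, X`` for volumes) with named channels and physical pixel/voxel
sizes in micrometres.  A :class:`SomaMask` wraps an instance label raster
(0 = background, positive integers = objects).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError


@dataclass
class ChannelImage:
    """Multi-channel raster with physical scale.

    Parameters
    ----------
    data : ndarray
        Channel-first array, ``(C, H, W)`` or ``(C, Z, Y, X)``.
    channels : list of str
        One name per channel (e.g. ``["ChAT", "NPY"]``).
    pixel_size : tuple of float
        Physical size of one pixel/voxel per spatial axis, in µm, in the
        same axis order as ``data`` (``(y, x)`` or ``(z, y, x)``).
    """

    data: np.ndarray
    channels: list[str]
    pixel_size: tuple[float, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim - 1 != len(self.pixel_size):
            raise ConfigError(
                f"pixel_size has {len(self.pixel_size)} entries for "
                f"{self.data.ndim - 1} spatial axes"
            )
        if self.data.shape[0] != len(self.channels):
            raise ConfigError(
                f"{len(self.channels)} channel names for {self.data.shape[0]} channels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ConfigError("channel names must be unique")
        if any(p <= 0 for p in self.pixel_size):
            raise ConfigError("pixel sizes must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        """Spatial shape (without the channel axis)."""
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel by name."""
        try:
            return self.data[self.channels.index(name)]
        except ValueError:
            raise ConfigError(
                f"channel {name!r} not in {self.channels}"
            ) from None


@dataclass
class SomaMask:
    """Instance segmentation labels plus physical scale."""

    labels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ConfigError("label image must be integer-typed")
        if self.labels.min() < 0:
            raise ConfigError("labels must be non-negative")

    @property
    def ids(self) -> np.ndarray:
        """Sorted positive label ids present in the raster."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def areas(self) -> dict[int, int]:
        """Pixel count per label."""
        ids, counts = np.unique(self.labels, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts) if i > 0}


def as_labels(mask: "SomaMask | np.ndarray") -> np.ndarray:
    """Accept either a SomaMask or a bare label array."""
    if isinstance(mask, SomaMask):
        return mask.labels
    return np.asarray(mask)
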