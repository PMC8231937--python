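"""Core in-memory containers shared across the pipeline.

A *tumor map* is a whole tissue section imaged once per stain with a
monochrome camera: one 8-bit grayscale grid per channel, mutually aligned.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

CHANNEL_HOECHST = "hoechst"
CHANNEL_CD31 = "cd31"

#: default physical resolution of the imaging system, μm per pixel
DEFAULT_PIXEL_SIZE = 0.75


class TumorMapError(Exception):
    """Base class for all domain errors raised by this package."""


class ConfigError(TumorMapError):
    """Invalid configuration or specification."""


@dataclass
class ChannelImage:
    """One stain's intensity grid.

    Parameters
    ----------
    pixels
        2-D integer array, values in [0, 255]; stored as uint8.
    channel
        Stain name, e.g. ``hoechst``, ``mkate``, ``her2``, ``cd31``.
    pixel_size
        Physical pixel size in μm/px.
    section_id
        Identifier of the tissue section this channel belongs to.
    """

    pixels: np.ndarray
    channel: str
    pixel_size: float = DEFAULT_PIXEL_SIZE
    section_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.size == 0:
            raise TumorMapError(
                f"channel {self.channel!r}: pixels must be a non-empty 2-D grid, "
                f"got shape {arr.shape}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.mod(arr, 1) == 0):
                raise TumorMapError(
                    f"channel {self.channel!r}: non-integer pixel values"
                )
            arr = arr.astype(np.int64)
        if arr.min() < 0 or arr.max() > 255:
            raise TumorMapError(
                f"channel {self.channel!r}: pixel values outside [0, 255]"
            )
        if self.pixel_size <= 0:
            raise TumorMapError("pixel_size must be positive")
        self.pixels = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class TumorMap:
    """A set of mutually aligned channels over one section."""

    channels: Mapping[str, ChannelImage]
    section_id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise TumorMapError("a TumorMap needs at least one channel")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise TumorMapError(f"channels have mismatched shapes: {sorted(shapes)}")
        sizes = {c.pixel_size for c in self.channels.values()}
        if len(sizes) != 1:
            raise TumorMapError(f"channels have mismatched pixel sizes: {sorted(sizes)}")
        for name, c in self.channels.items():
            if name != c.channel:
                raise TumorMapError(
                    f"channel key {name!r} does not match ChannelImage.channel {c.channel!r}"
                )
        self.channels = dict(self.channels)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def pixel_size(self) -> float:
        return next(iter(self.channels.values())).pixel_size

    def __getitem__(self, channel: str) -> ChannelImage:
        return self.channels[channel]

    def __contains__(self, channel: str) -> bool:
        return channel in self.channels
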