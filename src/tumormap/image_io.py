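"""Reading, writing, stitching and aligning channel images.

Channels travel as single-page grayscale TIFFs (one file per stain,
``<section>_<channel>.tif``); ROI label images as 16-bit TIFF with a CSV
metadata table; tiled fields of view are stitched into whole-section
montages by plain block placement (no overlap, no blending); channels of one
section are co-registered by integer-pixel translation maximizing normalized
cross-correlation against a reference channel.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .segmentation import ARTIFACT_LABEL, RoiSet
from .types import DEFAULT_PIXEL_SIZE, ChannelImage, TumorMap, TumorMapError

__all__ = [
    "TileGrid",
    "assemble_montage",
    "AlignmentReport",
    "align_channels",
    "read_channel",
    "write_channel",
    "read_section",
    "write_section",
    "read_roi_set",
    "write_roi_set",
    "write_profiles",
]

log = logging.getLogger(__name__)

# −1 (artifact) is stored as the uint16 maximum in label TIFFs
_ARTIFACT_STORED = np.uint16(65535)


@dataclass
class TileGrid:
    """Adjacent microscope fields of view awaiting stitching.

    ``tiles`` maps (grid_row, grid_col) to a ChannelImage; all tiles share
    one shape and one channel and the grid must be fully populated.
    """

    tiles: Mapping[tuple[int, int], ChannelImage]
    grid_shape: tuple[int, int]
    tile_shape: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        gr, gc = self.grid_shape
        expected = {(i, j) for i in range(gr) for j in range(gc)}
        missing = sorted(expected - set(self.tiles))
        if missing:
            raise TumorMapError(f"tile grid missing positions: {missing}")
        extra = sorted(set(self.tiles) - expected)
        if extra:
            raise TumorMapError(f"tile grid has out-of-range positions: {extra}")
        shapes = {t.shape for t in self.tiles.values()}
        if len(shapes) != 1:
            raise TumorMapError(f"heterogeneous tile shapes: {sorted(shapes)}")
        channels = {t.channel for t in self.tiles.values()}
        if len(channels) != 1:
            raise TumorMapError(f"tiles mix channels: {sorted(channels)}")
        self.tile_shape = next(iter(shapes))


def assemble_montage(grid: TileGrid) -> ChannelImage:
    """Stitch a fully populated tile grid into one whole-section image.

    Tile (i, j) occupies the half-open block starting at
    (i·tile_rows, j·tile_cols); tiles are assumed non-overlapping.
    """
    gr, gc = grid.grid_shape
    blocks = [[grid.tiles[(i, j)].pixels for j in range(gc)] for i in range(gr)]
    first = grid.tiles[(0, 0)]
    return ChannelImage(
        np.block(blocks), first.channel, first.pixel_size, first.section_id
    )


@dataclass
class AlignmentReport:
    """Applied integer shifts and per-channel diagnostic flags."""

    reference: str
    shifts: dict[str, tuple[int, int]]
    flags: dict[str, tuple[str, ...]]


def _shift_image(arr: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Translate by (dr, dc), filling vacated border pixels with 0."""
    out = np.zeros_like(arr)
    rows, cols = arr.shape
    rs_dst = slice(max(dr, 0), rows + min(dr, 0))
    cs_dst = slice(max(dc, 0), cols + min(dc, 0))
    rs_src = slice(max(-dr, 0), rows + min(-dr, 0))
    cs_src = slice(max(-dc, 0), cols + min(-dc, 0))
    out[rs_dst, cs_dst] = arr[rs_src, cs_src]
    return out


def align_channels(
    channels: Sequence[ChannelImage],
    reference: str,
    max_shift: int = 20,
) -> tuple[TumorMap, AlignmentReport]:
    """Co-register channels of one section by integer translation.

    Each non-reference channel is shifted by the translation within a
    ±``max_shift`` window that maximizes the normalized cross-correlation of
    its central crop against the reference. Correlation ties and degenerate
    (zero-variance) images resolve to shift (0, 0) with a flag; a best shift
    on the window boundary is flagged as possibly truncated.
    """
    from skimage.feature import match_template

    if len(channels) < 2:
        raise TumorMapError("alignment needs at least 2 channels")
    by_name = {c.channel: c for c in channels}
    if len(by_name) != len(channels):
        raise TumorMapError("duplicate channel names")
    if reference not in by_name:
        raise TumorMapError(f"reference channel {reference!r} not supplied")
    shapes = {c.shape for c in channels}
    if len(shapes) != 1:
        raise TumorMapError(f"channels have mismatched shapes: {sorted(shapes)}")

    ref_img = by_name[reference]
    ref = ref_img.pixels.astype(np.float64)
    m = min(int(max_shift), (min(ref.shape) - 3) // 2)
    m = max(m, 0)

    aligned: dict[str, ChannelImage] = {}
    shifts: dict[str, tuple[int, int]] = {}
    flags: dict[str, tuple[str, ...]] = {}
    for name, ci in by_name.items():
        fl: list[str] = []
        if name == reference:
            s = (0, 0)
        else:
            mov = ci.pixels.astype(np.float64)
            if m == 0:
                s = (0, 0)
                fl.append("window_collapsed")
            else:
                template = mov[m:-m, m:-m]
                if template.std() == 0 or ref.std() == 0:
                    s = (0, 0)
                    fl.append("degenerate_correlation")
                else:
                    resp = np.nan_to_num(match_template(ref, template), nan=-2.0)
                    best = resp.max()
                    cand = np.argwhere(resp >= best - 1e-9) - m
                    if len(cand) > 1:
                        fl.append("correlation_tie")
                    order = np.lexsort(
                        (cand[:, 1], cand[:, 0], np.abs(cand).sum(axis=1))
                    )
                    dr, dc = (int(v) for v in cand[order[0]])
                    s = (dr, dc)
                    if max(abs(dr), abs(dc)) == m:
                        fl.append("shift_on_window_boundary")
        pix = ci.pixels if s == (0, 0) else _shift_image(ci.pixels, *s)
        aligned[name] = ChannelImage(pix.copy(), name, ci.pixel_size, ci.section_id)
        shifts[name] = s
        flags[name] = tuple(fl)
    tm = TumorMap(aligned, ref_img.section_id)
    return tm, AlignmentReport(reference, shifts, flags)


def write_channel(image: ChannelImage, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, image.pixels, photometric="minisblack")
    return path


def read_channel(
    path,
    channel: str,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    section_id: str = "",
) -> ChannelImage:
    """Read one single-channel grayscale TIFF.

    8-bit data pass through untouched; 16-bit data are rescaled to 8-bit by
    max-normalization (v · 255/max, rounded half-up) and the rescale is
    logged. RGB TIFFs are rejected — split channels upstream.
    """
    arr = tifffile.imread(path)
    if arr.ndim == 3:
        raise TumorMapError(
            f"{path}: RGB/multichannel TIFF; separate stains into one "
            "single-channel grayscale file each"
        )
    if arr.ndim != 2:
        raise TumorMapError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        pix = arr
    elif arr.dtype == np.uint16:
        peak = int(arr.max())
        if peak == 0:
            pix = arr.astype(np.uint8)
        else:
            pix = np.floor(arr.astype(np.float64) * (255.0 / peak) + 0.5).astype(np.uint8)
        log.info("%s: 16-bit input rescaled to 8-bit by 255/%d", path, peak)
    else:
        raise TumorMapError(f"{path}: unsupported bit depth {arr.dtype}")
    return ChannelImage(pix, channel, pixel_size, section_id)


def write_section(tumor_map: TumorMap, directory) -> dict[str, Path]:
    """Write each channel as ``<section>_<channel>.tif``; return the paths."""
    directory = Path(directory)
    out = {}
    for name in sorted(tumor_map.channels):
        out[name] = write_channel(
            tumor_map[name], directory / f"{tumor_map.section_id}_{name}.tif"
        )
    return out


def read_section(
    paths: Mapping[str, object],
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    section_id: str = "",
) -> TumorMap:
    """Read a channel-name → TIFF-path mapping into a TumorMap."""
    channels = {
        name: read_channel(p, name, pixel_size, section_id)
        for name, p in paths.items()
    }
    shapes = {c.shape for c in channels.values()}
    if len(shapes) > 1:
        raise TumorMapError(f"channel shapes disagree across files: {sorted(shapes)}")
    return TumorMap(channels, section_id)


def write_roi_set(rois: RoiSet, tiff_path, csv_path) -> None:
    """Label image as uint16 TIFF (artifact −1 stored as 65535) + CSV table."""
    if rois.labels.max(initial=0) >= int(_ARTIFACT_STORED):
        raise TumorMapError("ROI ids ≥ 65535 cannot be stored in a 16-bit label TIFF")
    stored = rois.labels.astype(np.int64)
    stored[stored == ARTIFACT_LABEL] = int(_ARTIFACT_STORED)
    tiff_path = Path(tiff_path)
    tiff_path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(tiff_path, stored.astype(np.uint16), photometric="minisblack")
    table = rois.table.copy()
    n_artifact = int((rois.labels == ARTIFACT_LABEL).sum())
    if n_artifact:
        table = pd.concat(
            [table, pd.DataFrame([{
                "id": int(_ARTIFACT_STORED), "kind": "artifact", "organ": "",
                "area_px": n_artifact,
            }])],
            ignore_index=True,
        )
    Path(csv_path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(csv_path, index=False)


def read_roi_set(tiff_path, csv_path) -> RoiSet:
    stored = tifffile.imread(tiff_path).astype(np.int64)
    labels = stored.copy()
    labels[stored == int(_ARTIFACT_STORED)] = ARTIFACT_LABEL
    table = pd.read_csv(csv_path, comment="#")
    table = table[table["kind"] != "artifact"].reset_index(drop=True)
    table["organ"] = table["organ"].fillna("")
    return RoiSet(labels.astype(np.int32), table)


def write_profiles(profiles, path, header: str | None = None) -> Path:
    """Write a per-lesion profile table (DataFrame) to CSV.

    ``header`` is an optional comment line (e.g. recording seed and version)
    prefixed with ``#`` so readers can skip it.
    """
    frame = profiles if isinstance(profiles, pd.DataFrame) else pd.DataFrame(profiles)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        frame.to_csv(fh, index=False)
    return path
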