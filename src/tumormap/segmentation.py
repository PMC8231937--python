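"""Masks and regions of interest.

Produces the binary masks the metrics consume — a nuclei mask from the
Hoechst channel and a CD31-positive object mask — plus lesion ROI proposals
from the nuclei mask with a file-based manual-override mechanism that stands
in for interactive screening. Artifact regions carry label −1 and are
excluded from all downstream statistics.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk

from .types import ChannelImage, TumorMapError

__all__ = [
    "BinaryMask",
    "RoiSet",
    "mask_nuclei",
    "detect_cd31_objects",
    "propose_lesions",
    "apply_manual_rois",
]

ARTIFACT_LABEL = -1

# 8-connectivity throughout: diagonal neighbors belong to the same object
_EIGHT = np.ones((3, 3), int)

_TABLE_COLUMNS = ["id", "kind", "organ", "area_px"]


@dataclass
class BinaryMask:
    """A thresholded, size-filtered foreground mask for one channel."""

    pixels: np.ndarray
    source_channel: str
    threshold_used: int
    min_object_px: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, bool)


@dataclass
class RoiSet:
    """Integer label image plus a per-region metadata table.

    Label 0 is unassigned background, −1 marks excluded artifacts, and
    positive labels are regions listed in ``table`` with columns
    ``(id, kind, organ, area_px)`` where kind ∈ {lesion, normal, artifact}.
    """

    labels: np.ndarray
    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, np.int32)
        self.table = self.table.reset_index(drop=True)
        present = set(np.unique(self.labels[self.labels > 0]).tolist())
        listed = set(int(i) for i in self.table["id"])
        if present != listed:
            raise TumorMapError(
                f"RoiSet table ids {sorted(listed)} do not match positive labels "
                f"{sorted(present)}"
            )
        for _, row in self.table.iterrows():
            actual = int((self.labels == int(row["id"])).sum())
            if actual != int(row["area_px"]):
                raise TumorMapError(
                    f"RoiSet region {row['id']}: table area {row['area_px']} != "
                    f"label count {actual}"
                )

    @property
    def region_ids(self) -> list[int]:
        return [int(i) for i in self.table["id"]]

    @property
    def lesion_ids(self) -> list[int]:
        return [int(i) for i in self.table.loc[self.table["kind"] == "lesion", "id"]]

    def region_mask(self, roi_id: int) -> np.ndarray:
        return self.labels == roi_id

    def organ_of(self, roi_id: int) -> str:
        sel = self.table.loc[self.table["id"] == roi_id, "organ"]
        return str(sel.iloc[0]) if len(sel) else ""


def _resolve_threshold(pixels: np.ndarray, threshold) -> int:
    if threshold == "auto":
        if pixels.max() == pixels.min():
            raise TumorMapError("degenerate histogram; supply threshold")
        # Otsu classifies foreground as > t; +1 turns that into a ≥ cutoff
        return int(threshold_otsu(pixels)) + 1
    t = int(threshold)
    if not 0 <= t <= 255:
        raise TumorMapError(f"threshold outside [0, 255]: {t}")
    return t


def _filter_small(mask: np.ndarray, min_object_px: int) -> tuple[np.ndarray, int]:
    labels, n = ndi.label(mask, structure=_EIGHT)
    if n == 0:
        return mask, 0
    counts = np.bincount(labels.ravel())
    keep = counts >= min_object_px
    keep[0] = False
    return keep[labels], int(keep.sum())


def _threshold_mask(
    channel: ChannelImage, threshold, min_object_px: int
) -> tuple[BinaryMask, int]:
    if min_object_px < 1:
        raise TumorMapError("min_object_px must be ≥ 1")
    t = _resolve_threshold(channel.pixels, threshold)
    raw = channel.pixels >= t
    filtered, count = _filter_small(raw, min_object_px)
    return (
        BinaryMask(filtered, channel.channel, t, min_object_px),
        count,
    )


def mask_nuclei(
    hoechst: ChannelImage, threshold="auto", min_object_px: int = 4
) -> BinaryMask:
    """Threshold the Hoechst channel and keep particles of sufficient size.

    A pixel is foreground iff its intensity is ≥ the threshold and its
    8-connected component covers at least ``min_object_px`` pixels.
    ``threshold="auto"`` uses Otsu's method on the channel histogram.
    """
    mask, _ = _threshold_mask(hoechst, threshold, min_object_px)
    return mask


def detect_cd31_objects(
    cd31: ChannelImage, threshold="auto", min_object_px: int = 4
) -> tuple[BinaryMask, int]:
    """CD31-positive object mask plus the count of surviving components."""
    return _threshold_mask(cd31, threshold, min_object_px)


def propose_lesions(
    nuclei: BinaryMask, min_lesion_px: int = 500, closing_radius: int = 10
) -> RoiSet:
    """Propose lesion ROIs by fusing dense nuclei into solid regions.

    Morphological closing with a disk of ``closing_radius`` bridges gaps
    between nearby nuclei, holes are filled, and 8-connected components of at
    least ``min_lesion_px`` pixels become lesions. Ids are assigned by
    decreasing area (1 = largest). Automated proposals stand in for manual
    screening and are meant to be reviewed via :func:`apply_manual_rois`.
    """
    mask = nuclei.pixels
    if closing_radius > 0:
        mask = closing(mask, footprint=disk(closing_radius)).astype(bool)
    mask = ndi.binary_fill_holes(mask)
    labels, n = ndi.label(mask, structure=_EIGHT)
    out = np.zeros_like(labels, np.int32)
    rows = []
    if n:
        counts = np.bincount(labels.ravel())
        comps = [(lab, int(counts[lab])) for lab in range(1, n + 1)
                 if counts[lab] >= min_lesion_px]
        comps.sort(key=lambda t: (-t[1], t[0]))
        for new_id, (lab, area) in enumerate(comps, start=1):
            out[labels == lab] = new_id
            rows.append({"id": new_id, "kind": "lesion", "organ": "", "area_px": area})
    return RoiSet(out, pd.DataFrame(rows, columns=_TABLE_COLUMNS))


def apply_manual_rois(
    auto: RoiSet,
    manual_labels: np.ndarray,
    manual_table: pd.DataFrame | None = None,
) -> RoiSet:
    """Override automatic ROIs with a manually edited label image.

    Manual labels win wherever they are nonzero; label −1 marks artifacts to
    exclude downstream. Ids used by the manual mask must not collide with
    surviving automatic ids. ``manual_table`` may supply kind/organ metadata
    for manual ids; absent that they default to kind="lesion".
    """
    manual_labels = np.asarray(manual_labels, np.int32)
    if manual_labels.shape != auto.labels.shape:
        raise TumorMapError(
            f"manual label shape {manual_labels.shape} != auto {auto.labels.shape}"
        )
    out = auto.labels.copy()
    override = manual_labels != 0
    out[override] = manual_labels[override]

    manual_ids = set(np.unique(manual_labels[manual_labels > 0]).tolist())
    surviving_auto = set(np.unique(auto.labels[(auto.labels > 0) & ~override]).tolist())
    collision = manual_ids & surviving_auto
    if collision:
        raise TumorMapError(
            f"manual ids collide with automatic ids: {sorted(collision)}"
        )

    rows = []
    for rid in sorted(surviving_auto):
        meta = auto.table.loc[auto.table["id"] == rid].iloc[0]
        rows.append({
            "id": int(rid), "kind": meta["kind"], "organ": meta["organ"],
            "area_px": int((out == rid).sum()),
        })
    for rid in sorted(manual_ids):
        kind, organ = "lesion", ""
        if manual_table is not None and (manual_table["id"] == rid).any():
            meta = manual_table.loc[manual_table["id"] == rid].iloc[0]
            kind, organ = str(meta["kind"]), str(meta.get("organ", ""))
        rows.append({
            "id": int(rid), "kind": kind, "organ": organ,
            "area_px": int((out == rid).sum()),
        })
    table = pd.DataFrame(rows, columns=_TABLE_COLUMNS).sort_values("id")
    return RoiSet(out, table)
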