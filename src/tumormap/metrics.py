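"""Per-region quantities: intensity histograms, means, heat maps,
cellularity and vascular density.

Vascular density is defined here as the mean Euclidean distance from each
ROI pixel to the nearest CD31-positive pixel anywhere in the section —
larger values mean sparser vasculature. The nearest positive pixel may lie
outside the ROI: a lesion hugging organ vasculature is "close to vessels".
Distances are reported both in pixels and in μm.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as sps

from .segmentation import ARTIFACT_LABEL, BinaryMask, RoiSet
from .types import ChannelImage, TumorMap, TumorMapError

__all__ = [
    "IntensityHistogram",
    "HeatMapImage",
    "LesionProfile",
    "CorrelationResult",
    "intensity_histogram",
    "mean_intensity",
    "heatmap",
    "cellularity",
    "vessel_distance_map",
    "vascular_density",
    "VascularDensity",
    "profile_lesions",
    "profiles_to_frame",
    "correlate_density_expression",
]

HEAT_BACKGROUND, HEAT_WEAK, HEAT_MODERATE, HEAT_STRONG = 0, 1, 2, 3

FLAG_NO_VESSEL_IN_SECTION = "no_vessel_in_section"
FLAG_NO_VESSEL_IN_ROI = "no_vessel_in_roi"


def _roi_mask(rois: RoiSet, roi_id: int) -> np.ndarray:
    if roi_id == 0 or roi_id == ARTIFACT_LABEL:
        raise TumorMapError(f"roi_id must be a positive region id, got {roi_id}")
    mask = rois.labels == roi_id
    if not mask.any():
        raise TumorMapError(f"ROI {roi_id} is empty or absent")
    return mask


@dataclass
class IntensityHistogram:
    """Percent of ROI pixels at each of the 256 intensity levels."""

    bins: np.ndarray
    roi_id: int
    channel: str
    n_pixels: int

    def mean(self) -> float:
        """Histogram-weighted mean intensity, Σ v·bins[v]/100."""
        return float(np.arange(256) @ self.bins / 100.0)


def intensity_histogram(
    channel: ChannelImage, rois: RoiSet, roi_id: int
) -> IntensityHistogram:
    """Distribution of ROI pixels across intensity levels 0–255, in percent."""
    mask = _roi_mask(rois, roi_id)
    values = channel.pixels[mask]
    counts = np.bincount(values, minlength=256).astype(np.float64)
    return IntensityHistogram(
        counts / values.size * 100.0, int(roi_id), channel.channel, int(values.size)
    )


def mean_intensity(channel: ChannelImage, rois: RoiSet, roi_id: int) -> float:
    """Arithmetic mean intensity over the ROI."""
    mask = _roi_mask(rois, roi_id)
    return float(channel.pixels[mask].mean())


@dataclass
class HeatMapImage:
    """Weak/moderate/strong staining classes over ROI pixels.

    ``classes`` holds 0 = background (non-ROI), 1 = weak, 2 = moderate,
    3 = strong, split at the two intensity cutpoints in ``bin_edges``.
    """

    classes: np.ndarray
    bin_edges: tuple[int, int]
    channel: str

    def class_counts(self, rois: RoiSet, roi_id: int) -> dict[str, int]:
        mask = rois.labels == roi_id
        return {
            "weak": int((self.classes[mask] == HEAT_WEAK).sum()),
            "moderate": int((self.classes[mask] == HEAT_MODERATE).sum()),
            "strong": int((self.classes[mask] == HEAT_STRONG).sum()),
        }


def heatmap(
    channel: ChannelImage, rois: RoiSet, bin_edges: tuple[int, int] = (85, 170)
) -> HeatMapImage:
    """Classify ROI pixels as weak/moderate/strong staining.

    Default cutpoints split the 0–255 range into equal thirds; they are
    configurable and always carried in the result.
    """
    e1, e2 = bin_edges
    if not 0 < e1 < e2 < 255:
        raise TumorMapError(f"invalid heat-map edges {bin_edges}: need 0 < e1 < e2 < 255")
    v = channel.pixels
    classes = np.where(v >= e2, HEAT_STRONG, np.where(v >= e1, HEAT_MODERATE, HEAT_WEAK))
    classes = np.where(rois.labels > 0, classes, HEAT_BACKGROUND)
    return HeatMapImage(classes.astype(np.uint8), (int(e1), int(e2)), channel.channel)


def cellularity(
    nuclei: BinaryMask, hoechst: ChannelImage, rois: RoiSet, roi_id: int
) -> tuple[float, float]:
    """Percent of ROI area covered by the nuclei mask, and mean Hoechst
    intensity over the ROI."""
    mask = _roi_mask(rois, roi_id)
    if nuclei.pixels.shape != mask.shape:
        raise TumorMapError("nuclei mask shape does not match ROI labels")
    pct = 100.0 * float((nuclei.pixels & mask).sum()) / float(mask.sum())
    return pct, float(hoechst.pixels[mask].mean())


def vessel_distance_map(
    cd31_mask: np.ndarray, wrap: bool = False
) -> np.ndarray | None:
    """Euclidean distance from every pixel to the nearest CD31-positive pixel.

    Returns ``None`` if the mask is globally empty. With ``wrap=True`` the
    section is treated as a torus (distances wrap at the borders) — used to
    compare against boundary-free point-process theory.
    """
    mask = np.asarray(cd31_mask, bool)
    if not mask.any():
        return None
    if wrap:
        tiled = np.tile(mask, (3, 3))
        dist = ndi.distance_transform_edt(~tiled)
        r, c = mask.shape
        return dist[r : 2 * r, c : 2 * c]
    return ndi.distance_transform_edt(~mask)


@dataclass
class VascularDensity:
    mean_px: float
    mean_um: float
    flags: tuple[str, ...] = ()

    @property
    def defined(self) -> bool:
        return FLAG_NO_VESSEL_IN_SECTION not in self.flags


def vascular_density(
    cd31_mask: BinaryMask | np.ndarray,
    rois: RoiSet,
    roi_id: int,
    pixel_size: float = 0.75,
    wrap: bool = False,
    distance_map: np.ndarray | None = None,
) -> VascularDensity:
    """Mean nearest-CD31 distance over the ROI, in px and μm.

    If the CD31 mask is empty section-wide the value is undefined (NaN) and
    flagged ``no_vessel_in_section``; an ROI containing no positive pixel of
    its own still gets a defined value but is flagged ``no_vessel_in_roi``.
    ``distance_map`` lets callers reuse one distance transform across ROIs.
    """
    mask_arr = cd31_mask.pixels if isinstance(cd31_mask, BinaryMask) else np.asarray(cd31_mask, bool)
    roi = _roi_mask(rois, roi_id)
    if mask_arr.shape != roi.shape:
        raise TumorMapError("CD31 mask shape does not match ROI labels")
    if distance_map is None:
        distance_map = vessel_distance_map(mask_arr, wrap=wrap)
    if distance_map is None:
        return VascularDensity(float("nan"), float("nan"), (FLAG_NO_VESSEL_IN_SECTION,))
    flags: tuple[str, ...] = ()
    if not (mask_arr & roi).any():
        flags = (FLAG_NO_VESSEL_IN_ROI,)
    mean_px = float(distance_map[roi].mean())
    return VascularDensity(mean_px, mean_px * pixel_size, flags)


@dataclass
class LesionProfile:
    """Derived quantities for one lesion-kind region."""

    roi_id: int
    organ: str
    mean_intensity: dict[str, float]
    cellularity_pct: float
    cellularity_mean_intensity: float
    vascular_density_px: float
    vascular_density_um: float
    flags: tuple[str, ...] = ()


def profile_lesions(
    tumor_map: TumorMap,
    rois: RoiSet,
    nuclei_mask: BinaryMask,
    cd31_mask: BinaryMask,
) -> list[LesionProfile]:
    """One profile per lesion-kind region, ordered by roi_id.

    Per-metric failures are recorded as flags on the affected profile rather
    than aborting the whole section.
    """
    from .types import CHANNEL_HOECHST

    dist = vessel_distance_map(cd31_mask.pixels)
    profiles = []
    for roi_id in sorted(rois.lesion_ids):
        flags: list[str] = []
        means = {
            ch: mean_intensity(tumor_map[ch], rois, roi_id)
            for ch in sorted(tumor_map.channels)
        }
        if CHANNEL_HOECHST in tumor_map:
            pct, hmean = cellularity(
                nuclei_mask, tumor_map[CHANNEL_HOECHST], rois, roi_id
            )
        else:
            pct, hmean = float("nan"), float("nan")
            flags.append("no_hoechst_channel")
        vd = vascular_density(
            cd31_mask, rois, roi_id,
            pixel_size=tumor_map.pixel_size, distance_map=dist,
        )
        flags.extend(vd.flags)
        profiles.append(
            LesionProfile(
                roi_id=int(roi_id),
                organ=rois.organ_of(roi_id),
                mean_intensity=means,
                cellularity_pct=pct,
                cellularity_mean_intensity=hmean,
                vascular_density_px=vd.mean_px,
                vascular_density_um=vd.mean_um,
                flags=tuple(flags),
            )
        )
    return profiles


def profiles_to_frame(profiles: list[LesionProfile]) -> pd.DataFrame:
    """Flatten profiles to one row per lesion (``mean_<channel>`` columns)."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {"roi_id": p.roi_id, "organ": p.organ}
        for ch, m in sorted(p.mean_intensity.items()):
            row[f"mean_{ch}"] = m
        row["cellularity_pct"] = p.cellularity_pct
        row["cellularity_mean_intensity"] = p.cellularity_mean_intensity
        row["vascular_density_px"] = p.vascular_density_px
        row["vascular_density_um"] = p.vascular_density_um
        row["flags"] = ";".join(p.flags)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CorrelationResult:
    rho: float
    n: int
    p: float
    flags: tuple[str, ...] = ()


def correlate_density_expression(
    profiles: list[LesionProfile], marker: str
) -> CorrelationResult:
    """Spearman rank correlation of vascular density vs marker mean intensity.

    Lesions with undefined vascular density are excluded; at least 3 usable
    lesions are required. Ties are mid-ranked; the p-value uses the
    t-distribution approximation.
    """
    pairs = [
        (p.vascular_density_px, p.mean_intensity[marker])
        for p in profiles
        if np.isfinite(p.vascular_density_px)
    ]
    if len(pairs) < 3:
        raise TumorMapError(
            f"Spearman correlation needs ≥ 3 lesions with defined vascular "
            f"density, got {len(pairs)}"
        )
    x, y = np.array(pairs).T
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), len(pairs), float("nan"), ("zero_variance",))
    res = sps.spearmanr(x, y)
    return CorrelationResult(float(res.statistic), len(pairs), float(res.pvalue))
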