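"""Synthetic multi-channel tumor-section generator with retained ground truth.

The generator emulates whole-section "tumor maps" of metastasis-bearing mouse
organs: several circular lesions with lesion-specific marker means
(inter-metastatic heterogeneity) and an optional radial intensity gradient
(intra-tumoral heterogeneity); nuclei rendered as small filled disks, dense
inside lesions and sparser in normal tissue (Hoechst channel); CD31-positive
vessel cross-sections placed by a homogeneous spatial Poisson point process
with region-specific rate; additive Gaussian noise; 8-bit quantization.

Every latent quantity (lesion labels, per-lesion noiseless marker means,
nuclei area fractions, vessel rates and centers) is recorded as ground truth
so the downstream measurement chain can be validated by parameter recovery.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    CHANNEL_CD31,
    CHANNEL_HOECHST,
    DEFAULT_PIXEL_SIZE,
    ChannelImage,
    ConfigError,
    TumorMap,
)

__all__ = [
    "LesionSpec",
    "VesselFieldSpec",
    "SyntheticSpec",
    "GroundTruth",
    "generate_tumor_map",
    "spec_from_dict",
]


def _disk_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Row/col offsets of pixels strictly closer than ``radius`` to a center.

    The strict inequality makes ``radius = 1`` a single pixel, so point-like
    objects obey continuum point-process distance laws.
    """
    r = int(np.ceil(radius))
    rr, cc = np.mgrid[-r : r + 1, -r : r + 1]
    inside = rr * rr + cc * cc < radius * radius
    return rr[inside], cc[inside]


@dataclass
class LesionSpec:
    """One circular lesion.

    ``marker_means`` maps channel name to the lesion's mean intensity (0–255);
    ``gradient_amplitude`` modulates intensity radially within the lesion
    (center = mean + A, rim = mean − A; 0 disables); ``nuclei_density`` is the
    expected number of nuclei per 100×100 px patch.
    """

    id: int
    center: tuple[int, int]
    radius: float
    marker_means: Mapping[str, float] = field(default_factory=dict)
    gradient_amplitude: float = 0.0
    nuclei_density: float = 110.0


@dataclass
class VesselFieldSpec:
    """A Poisson field of CD31-positive disk-shaped vessel cross-sections.

    ``rate`` is the spatial intensity λ, expected objects per px², within
    ``region`` ("everywhere", "normal", or a lesion id).
    """

    rate: float
    object_radius: float = 3.0
    intensity: float = 200.0
    region: int | str = "everywhere"


@dataclass
class SyntheticSpec:
    """Full parameterization of one simulated section."""

    image_shape: tuple[int, int]
    lesions: Sequence[LesionSpec] = field(default_factory=list)
    vessel_fields: Sequence[VesselFieldSpec] = field(default_factory=list)
    background_marker_means: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0
    pixel_size: float = DEFAULT_PIXEL_SIZE
    nuclei_intensity: float = 220.0
    normal_nuclei_density: float = 30.0
    organ: str = ""
    section_id: str = "synthetic"

    @property
    def channels(self) -> list[str]:
        return sorted(self.background_marker_means)

    def validate(self) -> None:
        rows, cols = self.image_shape
        if rows < 64 or cols < 64:
            raise ConfigError(f"image_shape must be at least 64×64, got {self.image_shape}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        chans = set(self.channels)
        required = {CHANNEL_HOECHST, CHANNEL_CD31}
        if not required <= chans or len(chans) < 3:
            raise ConfigError(
                "channels must include 'hoechst' and 'cd31' plus at least one "
                f"marker channel; got {sorted(chans)}"
            )
        for ch, v in self.background_marker_means.items():
            if not 0 <= v <= 255:
                raise ConfigError(f"background mean for {ch!r} outside [0, 255]: {v}")
        ids = [l.id for l in self.lesions]
        if len(set(ids)) != len(ids):
            raise ConfigError(f"lesion ids must be unique, got {ids}")
        for les in self.lesions:
            if les.id <= 0:
                raise ConfigError(f"lesion id must be positive, got {les.id}")
            if les.radius < 3:
                raise ConfigError(f"lesion {les.id}: radius must be ≥ 3 px")
            if les.nuclei_density < 0:
                raise ConfigError(f"lesion {les.id}: nuclei_density must be ≥ 0")
            for ch, m in les.marker_means.items():
                if ch not in chans:
                    raise ConfigError(
                        f"lesion {les.id} references channel {ch!r} absent from "
                        f"channel set {sorted(chans)}"
                    )
                if not 0 <= m <= 255:
                    raise ConfigError(f"lesion {les.id}: mean for {ch!r} outside [0, 255]")
                lo = m - abs(les.gradient_amplitude)
                hi = m + abs(les.gradient_amplitude)
                if lo < 0 or hi > 255:
                    raise ConfigError(
                        f"lesion {les.id}: mean ± gradient_amplitude leaves [0, 255] "
                        f"for channel {ch!r} ({lo}..{hi})"
                    )
        # lesions may not overlap (disks are open, so tangent disks are fine)
        for i, a in enumerate(self.lesions):
            for b in self.lesions[i + 1 :]:
                d = float(np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1]))
                if d < a.radius + b.radius:
                    raise ConfigError(
                        f"lesions {a.id} and {b.id} overlap "
                        f"(center distance {d:.1f} < {a.radius + b.radius:.1f})"
                    )
        for vf in self.vessel_fields:
            if vf.rate < 0:
                raise ConfigError("vessel rate must be ≥ 0")
            if vf.object_radius < 1:
                raise ConfigError("vessel object_radius must be ≥ 1")
            if not 0 <= vf.intensity <= 255:
                raise ConfigError("vessel intensity outside [0, 255]")
            if vf.region not in ("everywhere", "normal") and vf.region not in ids:
                raise ConfigError(
                    f"vessel field references unknown region {vf.region!r}; "
                    f"valid: 'everywhere', 'normal', or a lesion id in {ids}"
                )


@dataclass
class GroundTruth:
    """Latent values retained from a simulation.

    ``roi_labels`` assigns every pixel its lesion id (0 = normal/background);
    ``lesion_table`` holds, per lesion, the noiseless spatial marker means,
    the exact nuclei area fraction of the rendered mask, and the vessel rate
    in force inside the lesion; ``vessel_centers`` are all placed centers.
    """

    roi_labels: np.ndarray
    lesion_table: pd.DataFrame
    vessel_centers: np.ndarray
    nuclei_mask: np.ndarray


def _stamp_disks(
    target: np.ndarray,
    centers_r: np.ndarray,
    centers_c: np.ndarray,
    radii: np.ndarray,
) -> None:
    rows, cols = target.shape
    offsets = {float(r): _disk_offsets(float(r)) for r in np.unique(radii)}
    for r0, c0, rad in zip(centers_r, centers_c, radii):
        orr, occ = offsets[float(rad)]
        rr = orr + r0
        cc = occ + c0
        ok = (rr >= 0) & (rr < rows) & (cc >= 0) & (cc < cols)
        target[rr[ok], cc[ok]] = True


def generate_tumor_map(spec: SyntheticSpec) -> tuple[TumorMap, GroundTruth]:
    """Render one section and return the channel images plus ground truth.

    Deterministic for a fixed ``spec.seed``: lesions are drawn in list order,
    then nuclei (lesions in order, then normal tissue), then vessel fields in
    order, then per-channel noise in sorted channel order.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_shape
    shape = (rows, cols)
    channels = spec.channels

    fields = {
        ch: np.full(shape, float(spec.background_marker_means[ch]))
        for ch in channels
    }
    roi_labels = np.zeros(shape, np.int32)
    rr_grid, cc_grid = np.mgrid[0:rows, 0:cols]

    lesion_masks: dict[int, np.ndarray] = {}
    for les in spec.lesions:
        d = np.hypot(rr_grid - les.center[0], cc_grid - les.center[1])
        mask = d < les.radius
        lesion_masks[les.id] = mask
        roi_labels[mask] = les.id
        for ch, mean in les.marker_means.items():
            fields[ch][mask] = mean + les.gradient_amplitude * (
                1.0 - 2.0 * d[mask] / les.radius
            )
    any_lesion = roi_labels > 0

    # nuclei: Poisson-placed centers, disk radius uniform on {2, 3, 4}
    nuclei_mask = np.zeros(shape, bool)
    for les in spec.lesions:
        idx = np.flatnonzero(lesion_masks[les.id])
        n = int(rng.poisson(les.nuclei_density / 1e4 * idx.size))
        if n:
            picks = rng.choice(idx, size=n)
            radii = rng.integers(2, 5, size=n)
            _stamp_disks(nuclei_mask, picks // cols, picks % cols, radii)
    normal_idx = np.flatnonzero(~any_lesion)
    n = int(rng.poisson(spec.normal_nuclei_density / 1e4 * normal_idx.size))
    if n:
        picks = rng.choice(normal_idx, size=n)
        radii = rng.integers(2, 5, size=n)
        _stamp_disks(nuclei_mask, picks // cols, picks % cols, radii)
    fields[CHANNEL_HOECHST] = np.maximum(
        fields[CHANNEL_HOECHST],
        np.where(nuclei_mask, float(spec.nuclei_intensity), 0.0),
    )

    # vessels: one homogeneous Poisson process per field, max-composited
    all_centers: list[np.ndarray] = []
    for vf in spec.vessel_fields:
        if vf.region == "everywhere":
            region = np.ones(shape, bool)
        elif vf.region == "normal":
            region = ~any_lesion
        else:
            region = lesion_masks[vf.region]
        idx = np.flatnonzero(region)
        n = int(rng.poisson(vf.rate * idx.size))
        vmask = np.zeros(shape, bool)
        if n:
            picks = rng.choice(idx, size=n)
            cr, cc_ = picks // cols, picks % cols
            _stamp_disks(vmask, cr, cc_, np.full(n, vf.object_radius))
            all_centers.append(np.column_stack([cr, cc_]))
        fields[CHANNEL_CD31] = np.where(
            vmask & (fields[CHANNEL_CD31] < vf.intensity),
            float(vf.intensity),
            fields[CHANNEL_CD31],
        )
    vessel_centers = (
        np.concatenate(all_centers) if all_centers else np.empty((0, 2), int)
    )

    # per-lesion latent values, recorded before noise/quantization
    lesion_rows = []
    for les in spec.lesions:
        mask = lesion_masks[les.id]
        area = int(mask.sum())
        row: dict[str, object] = {
            "lesion_id": les.id,
            "organ": spec.organ,
            "area_px": area,
            "true_nuclei_fraction": float(nuclei_mask[mask].sum()) / area,
            "true_vessel_rate": float(
                sum(
                    vf.rate
                    for vf in spec.vessel_fields
                    if vf.region == "everywhere" or vf.region == les.id
                )
            ),
        }
        for ch in channels:
            row[f"true_mean_{ch}"] = float(fields[ch][mask].mean())
        lesion_rows.append(row)
    columns = [
        "lesion_id", "organ", "area_px", "true_nuclei_fraction", "true_vessel_rate",
    ] + [f"true_mean_{ch}" for ch in channels]
    lesion_table = pd.DataFrame(lesion_rows, columns=columns)

    out = {}
    for ch in channels:
        arr = fields[ch]
        if spec.noise_sd > 0:
            arr = arr + rng.normal(0.0, spec.noise_sd, shape)
        pix = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
        out[ch] = ChannelImage(pix, ch, spec.pixel_size, spec.section_id)

    tm = TumorMap(out, spec.section_id)
    gt = GroundTruth(roi_labels, lesion_table, vessel_centers, nuclei_mask)
    return tm, gt


def spec_from_dict(d: Mapping) -> SyntheticSpec:
    """Build a :class:`SyntheticSpec` from a flat config mapping (e.g. TOML).

    Expected keys: ``image_shape``, ``background`` (channel → mean), optional
    ``lesions`` and ``vessels`` lists, plus the scalar fields of
    :class:`SyntheticSpec` under their own names.
    """
    try:
        lesions = [
            LesionSpec(
                id=int(l["id"]),
                center=(int(l["center"][0]), int(l["center"][1])),
                radius=float(l["radius"]),
                marker_means={k: float(v) for k, v in l.get("means", {}).items()},
                gradient_amplitude=float(l.get("gradient_amplitude", 0.0)),
                nuclei_density=float(l.get("nuclei_density", 110.0)),
            )
            for l in d.get("lesions", [])
        ]
        vessels = [
            VesselFieldSpec(
                rate=float(v["rate"]),
                object_radius=float(v.get("object_radius", 3.0)),
                intensity=float(v.get("intensity", 200.0)),
                region=(
                    v.get("region", "everywhere")
                    if v.get("region", "everywhere") in ("everywhere", "normal")
                    else int(v["region"])
                ),
            )
            for v in d.get("vessels", [])
        ]
        return SyntheticSpec(
            image_shape=(int(d["image_shape"][0]), int(d["image_shape"][1])),
            lesions=lesions,
            vessel_fields=vessels,
            background_marker_means={
                k: float(v) for k, v in d.get("background", {}).items()
            },
            noise_sd=float(d.get("noise_sd", 0.0)),
            seed=int(d.get("seed", 0)),
            pixel_size=float(d.get("pixel_size", DEFAULT_PIXEL_SIZE)),
            nuclei_intensity=float(d.get("nuclei_intensity", 220.0)),
            normal_nuclei_density=float(d.get("normal_nuclei_density", 30.0)),
            organ=str(d.get("organ", "")),
            section_id=str(d.get("section_id", "synthetic")),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid synthetic section config: {exc}") from exc
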