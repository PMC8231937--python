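import numpy as np
import pandas as pd
import pytest

from tumormap import (
    ChannelImage,
    LesionSpec,
    RoiSet,
    SyntheticSpec,
    VesselFieldSpec,
    generate_tumor_map,
)


def make_spec(**overrides) -> SyntheticSpec:
    """A small two-lesion section; keyword overrides replace any field."""
    base = dict(
        image_shape=(192, 192),
        lesions=[
            LesionSpec(1, (60, 60), 28, {"her2": 180}),
            LesionSpec(2, (130, 130), 28, {"her2": 60}),
        ],
        vessel_fields=[VesselFieldSpec(rate=5e-4, object_radius=2, intensity=200)],
        background_marker_means={"hoechst": 10, "cd31": 5, "her2": 5},
        noise_sd=0.0,
        seed=11,
    )
    base.update(overrides)
    return SyntheticSpec(**base)


@pytest.fixture(scope="session")
def small_section():
    """Zero-noise two-lesion section with ground truth (session-cached)."""
    return generate_tumor_map(make_spec())


@pytest.fixture(scope="session")
def noisy_section():
    return generate_tumor_map(make_spec(noise_sd=10.0, seed=5))


def roi_from_labels(labels: np.ndarray, organ: str = "") -> RoiSet:
    """Wrap a label image in a RoiSet, deriving the table from the labels."""
    labels = np.asarray(labels, np.int32)
    ids = sorted(np.unique(labels[labels > 0]).tolist())
    table = pd.DataFrame({
        "id": ids,
        "kind": "lesion",
        "organ": organ,
        "area_px": [int((labels == i).sum()) for i in ids],
    })
    return RoiSet(labels, table)


def channel(pixels, name="her2", **kw) -> ChannelImage:
    return ChannelImage(np.asarray(pixels), name, **kw)


def brute_force_mean_nearest_distance(mask: np.ndarray, roi: np.ndarray) -> float:
    """All-pairs nearest-distance oracle, independent of the EDT route."""
    pos = np.argwhere(mask)
    roi_px = np.argwhere(roi)
    d = np.sqrt(
        ((roi_px[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    ).min(axis=1)
    return float(d.mean())
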