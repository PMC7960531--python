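import numpy as np
import pytest

from ramanmargin.synthetic import (
    SceneSpec,
    VideoGenSpec,
    default_scene,
    generate_class_spectra,
    generate_probe_video,
    muscle_spec,
    phantom_spec,
    smooth_trajectory,
)
from ramanmargin.tracking import ProbeGeometry, calibrate_hsv
from ramanmargin.workflow import preprocess_dataset


@pytest.fixture(scope="session")
def small_scene() -> SceneSpec:
    """320×240 scene with a central elliptical lesion at 0.5 mm/px."""
    return default_scene(width_px=320, height_px=240)


@pytest.fixture(scope="session")
def small_video(small_scene):
    """12-frame probe video over the small scene, frame 5 occluded."""
    video = VideoGenSpec(
        n_frames=12,
        trajectory=smooth_trajectory(12, 320, 240, margin_px=115.0),
        occluded_frames=frozenset({5}),
        seed=7,
    )
    frames, truth = generate_probe_video(small_scene, video)
    return {"video": video, "frames": frames, "truth": truth}


@pytest.fixture(scope="session")
def calibrated(small_video):
    truth = small_video["truth"]
    specs = calibrate_hsv(
        small_video["frames"][0],
        [truth.loc[0, ["mx1", "my1"]].tolist(), truth.loc[0, ["mx2", "my2"]].tolist()],
    )
    return specs


@pytest.fixture(scope="session")
def geometry() -> ProbeGeometry:
    return ProbeGeometry(marker_separation_mm=20.0, tip_offset_mm=30.0)


@pytest.fixture(scope="session")
def two_class_dataset():
    """25+25 preprocessed muscle vs non-fluorescent phantom spectra."""
    spectra = generate_class_spectra(muscle_spec(), 25, seed=11)
    spectra += generate_class_spectra(phantom_spec(0.0), 25, seed=12)
    labels = ["muscle"] * 25 + ["phantom_0uM"] * 25
    return preprocess_dataset(spectra, labels)
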