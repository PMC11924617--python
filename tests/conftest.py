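import numpy as np
import pytest

from weakfoot import (
    GaitSimConfig,
    Recording,
    SensorLayout,
    default_layout,
    simulate_subject,
)


@pytest.fixture(scope="session")
def layout2():
    """Two sensors per foot at (0, 0) and (0, 100) mm."""
    coords = ((0.0, 0.0), (0.0, 100.0))
    return {side: SensorLayout(side, coords) for side in ("left", "right")}


@pytest.fixture(scope="session")
def quiet_cfg():
    """Simulator config with every stochastic term switched off."""
    return GaitSimConfig(
        step_cv=0.0, noise_add=0.0, noise_mult=0.0, shape_sigma=0.0,
        signature_sigma=0.0, fatigue=0.0, drift_sigma=0.0,
    )


@pytest.fixture(scope="session")
def hr_recording(quiet_cfg):
    """Deterministic persistent-weak-foot recording (left weak, 122 steps)."""
    from dataclasses import replace
    cfg = replace(quiet_cfg, phenotype="DWF_HR", weak_side="left",
                  attenuation=0.5, total_steps=122)
    return simulate_subject(cfg, seed=7, subject_id="hr0")


def square_wave_recording(layout, bursts, rate=100.0, frames_per=10, gap=20):
    """Alternating per-foot pressure bursts for segmentation tests."""
    n = layout["left"].n
    total = bursts * (frames_per + gap) + gap
    left = np.zeros((total, n))
    right = np.zeros((total, n))
    for i in range(bursts):
        start = gap + i * (frames_per + gap)
        target = left if i % 2 == 0 else right
        target[start : start + frames_per, :] = 1.0
    return Recording(subject_id="sq", label="unlabeled", rate=rate,
                     left=left, right=right, layout=layout)


@pytest.fixture
def square_recording(layout2):
    return square_wave_recording(layout2, bursts=4)
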