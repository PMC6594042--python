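"""Shared fixtures.

The expensive synthetic recordings are session-scoped so every test that
needs a rendered movie (unit, invariant and acceptance checks alike)
shares one render + one analysis per condition.
"""

from __future__ import annotations

import numpy as np
import pytest

from csdquant.pipeline import (
    RecordingMetrics,
    analyze_recording,
    recover_preset,
    simulate_recording,
)
from csdquant.synthetic import PRESET_NAMES, build_preset

RECOVERY_SEEDS = list(range(1, 11))


@pytest.fixture(scope="session")
def noiseless_runs() -> dict[str, tuple]:
    """Noiseless render + full analysis for every packaged preset.

    Returns {preset_name: (SimulatedRecording, RecordingMetrics)}.
    """
    out = {}
    for name in PRESET_NAMES:
        preset = build_preset(name)
        rec = simulate_recording(preset, noiseless=True)
        rm = analyze_recording(
            rec.stack,
            rec.spec,
            onset_s=rec.spec.onset_s,
            awake=preset.is_awake,
            phantom=rec.phantom,
            recording_id=name,
        )
        out[name] = (rec, rm)
    return out


@pytest.fixture(scope="session")
def noisy_recovery() -> dict[str, "pd.DataFrame"]:
    """Default-noise 10-seed recovery for the presets under study.

    Awake recovery runs the full awake protocol, including event-onset
    detection from the neuronal channel.
    """
    return {
        name: recover_preset(name, seeds=RECOVERY_SEEDS)
        for name in ("wt_anesthetized", "ko_anesthetized", "wt_awake")
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
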