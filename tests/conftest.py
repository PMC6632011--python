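import numpy as np
import pandas as pd
import pytest

from ffcpredict import (
    REGISTRY,
    EffectSpec,
    SynthConfig,
    generate_dataset,
)

# short videos keep unit tests fast; the generator's defaults (180 s, 25 fps)
# are exercised where the study structure itself is under test


@pytest.fixture(scope="session")
def tiny_dataset():
    """4 sessions x 3 groups, strong late effect: separable but fast."""
    cfg = SynthConfig(n_sessions=4, groups_per_session=3, duration_s=12.0, fps=25, seed=11)
    return generate_dataset(cfg, EffectSpec(effect_size=2.0))


@pytest.fixture(scope="session")
def null_dataset():
    """3 sessions x 4 groups, no label effect."""
    cfg = SynthConfig(n_sessions=3, groups_per_session=4, duration_s=8.0, fps=25, seed=7)
    return generate_dataset(cfg, EffectSpec(effect_size=0.0))


def make_feature_frame(n_rows, rng=None, success=None, confidence=None):
    """A valid DataFrame in the upstream CSV dialect."""
    rng = rng or np.random.default_rng(0)
    df = pd.DataFrame(
        {
            "frame": np.arange(1, n_rows + 1),
            "face_id": 0,
            "timestamp": np.arange(n_rows) / 25.0,
            "confidence": np.ones(n_rows) if confidence is None else confidence,
            "success": np.ones(n_rows, dtype=int) if success is None else success,
        }
    )
    for ch in REGISTRY.channels:
        if ch.kind == "au_presence":
            df[ch.name] = rng.integers(0, 2, n_rows).astype(float)
        elif ch.kind == "au_intensity":
            df[ch.name] = rng.uniform(0, 5, n_rows)
        else:
            df[ch.name] = rng.normal(0, 0.2, n_rows)
    return df
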