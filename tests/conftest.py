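import numpy as np
import pytest

from neuromat import (LibrarySpec, ThresholdConfig, preset, render_field,
                      score_screen, simulate_screen_features)


@pytest.fixture(scope="session")
def thr_cfg():
    return ThresholdConfig()


@pytest.fixture(scope="session")
def rat_field():
    """One rat-day-14 benchmark field (noisy, default geometry)."""
    return render_field(preset("rat_day14", seed=1))


@pytest.fixture(scope="session")
def screen_plates():
    """Default 2,688-compound duplicate screen with planted toxic and hits."""
    return simulate_screen_features(LibrarySpec(seed=11))


@pytest.fixture(scope="session")
def screen_result(screen_plates):
    return score_screen(screen_plates)


@pytest.fixture(scope="session")
def screen_truth(screen_plates):
    t = screen_plates.truth.set_index("compound_id")["label"]
    return {
        "toxic": set(t[t == "toxic"].index),
        "hit": set(t[t == "hit"].index),
        "inert": set(t[t == "inert"].index),
    }
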