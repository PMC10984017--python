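import numpy as np
import pytest

import isoensemble as iso


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_population():
    """40 neurons with planted alcohol/water responses and aligned tensors."""
    events = {
        "alcohol": np.arange(15) * 40.0 + 20.0,
        "water": np.arange(15) * 40.0 + 40.0,
    }
    traces, ft, gt = iso.synth.gen_calcium_population(
        40, events, duration_s=650.0, seed=99
    )
    tensors = {
        cls: iso.neural.zscore_baseline(
            iso.neural.align_events(traces, ft, t, event_class=cls)
        )
        for cls, t in events.items()
    }
    return {"traces": traces, "frame_times": ft, "events": events,
            "ground_truth": gt, "tensors": tensors}
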