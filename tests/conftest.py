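import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_threshold_table():
    """Complete 5-subject factorial table with pure-noise cell values."""
    import pandas as pd
    from blursim.conditions import BLUR_LEVELS, CUE_LEVELS, LOCATIONS

    gen = np.random.default_rng(777)
    rows = []
    for s in range(5):
        for loc in LOCATIONS:
            for blur in BLUR_LEVELS:
                for cue in CUE_LEVELS:
                    rows.append(
                        dict(
                            subject=f"S{s + 1}",
                            location=loc,
                            blur=blur,
                            cue=cue,
                            mad=gen.normal(5.0, 1.0),
                            rt=gen.normal(400.0, 30.0),
                        )
                    )
    return pd.DataFrame(rows)
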