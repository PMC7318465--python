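import numpy as np
import pytest

from nucleofoci import PipelineConfig, SyntheticSpec


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def small_spec() -> SyntheticSpec:
    """A desk-scale field: 320x320 px, 6 nuclei — fast to render and segment."""
    return SyntheticSpec(image_shape=(320, 320), n_nuclei=6, n_nuclei_sd=0.0)


@pytest.fixture
def noise_free_spec() -> SyntheticSpec:
    return SyntheticSpec(image_shape=(320, 320), n_nuclei=6, n_nuclei_sd=0.0,
                         read_noise_sd=0.0, dapi_sd=0.0, safb_noise_sd=0.0)


def match_focus_counts(truth_nuclei, records) -> list[tuple[int, int]]:
    """Pair each true nucleus with the nearest automated nucleus and return
    (true count, automated count) pairs."""
    pairs = []
    for _, row in truth_nuclei.iterrows():
        best = min(records, key=lambda n: (n.centroid_rc[0] - row.center_r) ** 2
                   + (n.centroid_rc[1] - row.center_c) ** 2)
        d2 = ((best.centroid_rc[0] - row.center_r) ** 2
              + (best.centroid_rc[1] - row.center_c) ** 2)
        assert d2 < 16.0, "no automated nucleus near a true nucleus"
        pairs.append((int(row.focus_count), best.focus_count))
    return pairs
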