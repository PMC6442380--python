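import numpy as np
import pytest

from cohesin_occupancy import BinnedTrack, SimulationConfig, generate_layout


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Reduced genome that keeps every layout rule active but runs fast."""
    return SimulationConfig(
        chromosome_lengths={"chrA": 500_000, "chrB": 300_000},
        n_origins=4, n_enhancers=20, n_promoters=60, n_pres=5, n_random=30,
        n_transcripts=20, transcript_length=6_000,
        transcript_min_origin_distance=12_000,
        origin_min_separation=60_000, enhancer_origin_sd=8_000,
        promoter_proximal_fraction=0.25, proximal_max_distance=12_000,
        distal_min_distance=30_000, seed=11)


@pytest.fixture(scope="session")
def small_layout(small_config):
    return generate_layout(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_track(values_by_chrom, bin_width=50, lengths=None) -> BinnedTrack:
    values = {c: np.asarray(v, dtype=float) for c, v in values_by_chrom.items()}
    if lengths is None:
        lengths = {c: v.size * bin_width for c, v in values.items()}
    return BinnedTrack(bin_width, lengths, values)
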