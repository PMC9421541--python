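import numpy as np
import pytest

from microspect import ClusterConfig, SyntheticConfig, simulate_cohort
from microspect.clustering import MicrostateMapSet
from microspect.templates import SCHEMATIC_1020, make_canonical_templates


@pytest.fixture(scope="session")
def templates():
    return make_canonical_templates()


@pytest.fixture(scope="session")
def montage():
    return list(SCHEMATIC_1020)


@pytest.fixture(scope="session")
def template_maps(templates, montage):
    """Canonical templates wrapped as a grand-level map set."""
    return MicrostateMapSet(
        maps=templates,
        labels=list("ABCDE"),
        channel_labels=montage,
        level="grand",
    )


@pytest.fixture(scope="session")
def clean_subject():
    """One noise-free subject with ground truth (no group effect)."""
    from microspect import simulate_subject

    cfg = SyntheticConfig(
        duration=40.0,
        n_per_group=2,
        snr=np.inf,
        seed=101,
        group2_mapE_duration_scale=1.0,
        group2_mapE_occurrence_scale=1.0,
    )
    rec, truth = simulate_subject(cfg, 1, 0)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def recovery_cohort():
    """Small high-SNR cohort for parameter-recovery checks."""
    cfg = SyntheticConfig(duration=30.0, n_per_group=4, snr=10, seed=31)
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def fast_cluster_cfg():
    return ClusterConfig(k_range=(5,), n_repetitions=8, max_gfp_peaks=400, seed=3)
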