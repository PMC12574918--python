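import pandas as pd
import pytest

from tigermove import SimConfig, run_cohort

RECOVERY_SEEDS = (1, 2, 3, 4, 5)


def small_config(seed: int = 7, **kw) -> SimConfig:
    """A fast-running simulator configuration for unit tests."""
    base = dict(
        seed=seed,
        cohort_size=8,
        n_stations_per_array=(5, 4),
        study_end="2018-09-30",
        min_track_days=60,
    )
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def bundles():
    """Full-size pipeline runs at the study conditions, one per seed."""
    return {
        seed: run_cohort(SimConfig(seed=seed), null_reps=120)
        for seed in RECOVERY_SEEDS
    }


@pytest.fixture(scope="session")
def bundle(bundles):
    return bundles[RECOVERY_SEEDS[0]]


@pytest.fixture()
def toy_tags():
    return pd.DataFrame(
        {
            "shark_id": ["S1", "S2"],
            "tag_id": ["T1", "T2"],
            "tagging_datetime": pd.to_datetime(["2018-02-06", "2018-03-01"]),
            "tagging_array": ["NewProvidence", "GreatExuma"],
            "fl_tagging_cm": [200.0, 250.0],
            "sex": ["F", "M"],
            "claspers_calcified": [False, True],
            "min_delay_s": [60.0, 60.0],
            "max_delay_s": [180.0, 180.0],
        }
    )


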