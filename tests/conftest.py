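import numpy as np
import pandas as pd
import pytest

from lionwelfare import DEFAULT_ETHOGRAM, WelfareStudy, ZoneMap
from lionwelfare.simulate import GeneratorConfig, generate_study


@pytest.fixture(scope="session")
def ethogram():
    return DEFAULT_ETHOGRAM


@pytest.fixture()
def zone_map():
    return ZoneMap(enclosure_id="en01")


@pytest.fixture()
def make_scans():
    """Factory for small scan frames: pass parallel per-minute lists."""

    def _make(
        behaviours,
        zones=None,
        minutes=None,
        contexts=None,
        subject_id="a1",
        session_id="a1-s001",
        time_block="0500-1100",
    ) -> pd.DataFrame:
        n = len(behaviours)
        return pd.DataFrame(
            {
                "subject_id": subject_id,
                "session_id": session_id,
                "time_block": time_block,
                "minute_index": list(minutes) if minutes is not None else list(range(n)),
                "behaviour": list(behaviours),
                "zone_id": list(zones) if zones is not None else ["z01"] * n,
                "context": list(contexts) if contexts is not None else [""] * n,
            }
        )

    return _make


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic study: 38 subjects (3 planted inconsistents), 4 sessions."""
    config = GeneratorConfig(sessions_per_subject=4, n_inconsistent=3)
    return generate_study(config, seed=7)


@pytest.fixture(scope="session")
def small_results(small_bundle):
    study = WelfareStudy(
        small_bundle.roster, small_bundle.scans, small_bundle.ratings, small_bundle.trials
    )
    return study.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
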