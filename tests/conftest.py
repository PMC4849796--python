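import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seapatch.survey_model import SurveyBin, SurveyLine

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_line(
    counts,
    length_km=3.0,
    strip_width_m=200.0,
    depths=None,
    sst=None,
    sss=None,
    line_id="1",
    cruise_id="c01",
    env=None,
):
    """Build a SurveyLine from per-bin counts with simple defaults."""
    n = len(counts)
    lengths = [length_km] * n if np.isscalar(length_km) else list(length_km)
    strips = [strip_width_m] * n if np.isscalar(strip_width_m) else list(strip_width_m)
    depths = depths if depths is not None else [100.0 + 50.0 * i for i in range(n)]
    sst = sst if sst is not None else [13.0] * n
    sss = sss if sss is not None else [33.5] * n
    bins = [
        SurveyBin(
            line_id=line_id,
            cruise_id=cruise_id,
            bin_index=i,
            length_km=lengths[i],
            strip_width_m=strips[i],
            count=int(counts[i]),
            depth_m=depths[i],
            lat_deg=37.9,
            lon_deg=-123.0 + 0.03 * i,
            sst_c=sst[i],
            sss=sss[i],
        )
        for i in range(n)
    ]
    return SurveyLine(
        line_id=line_id,
        cruise_id=cruise_id,
        bins=bins,
        julian_day=150.0,
        cumulative_julian_day=150.0,
        env=env or {},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20160428)


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """A written default synthetic survey fixture shared across tests."""
    from seapatch.synthetic_data import SimConfig, simulate_survey

    out = tmp_path_factory.mktemp("fixture")
    fixture = simulate_survey(SimConfig(seed=11), out_dir=out)
    return out, fixture
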