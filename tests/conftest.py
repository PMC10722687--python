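import pytest

from ssnc_invest.synthetic import tanzania_fixture


@pytest.fixture(scope="session")
def tz():
    """The packaged Tanzania worked example."""
    return tanzania_fixture()


@pytest.fixture(scope="session")
def tz_projection(tz):
    from ssnc_invest.impact import project_impact

    return project_impact(tz.country, tz.causes, tz.interventions, tz.trajectories(), tz.end_year)
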