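import pytest
from shapely.geometry import box

from cortimap.protocol import StimProtocol, StimTrial
from cortimap.sites import StimSite
from cortimap.taxonomy import MovementLabel, default_taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture(scope="session")
def protocol():
    return StimProtocol()


def make_site(
    site_id,
    position,
    parts=(),
    case_id="K1",
    field="unassigned",
    bracket=(50.0, 60.0),
    trials=None,
    **kw,
):
    """Build a site; ``parts`` become movements with a (no, yes) staircase
    at ``bracket`` unless explicit ``trials`` are given."""
    labels = tuple(MovementLabel(p) if isinstance(p, str) else p for p in parts)
    if trials is None:
        n, l = bracket
        trials = {
            lab: (StimTrial(n, False), StimTrial(l, True)) for lab in labels
        }
    return StimSite(
        case_id=case_id,
        site_id=site_id,
        position=position,
        field=field,
        movements=frozenset(labels),
        trials=trials,
        **kw,
    )


@pytest.fixture
def unit_square():
    return box(0.0, 0.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def small_study():
    """A compact deterministic four-case study shared across tests."""
    from cortimap.simulate import SimParams, simulate_study

    return simulate_study(SimParams(seed=11, n_sites=80), 4)
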