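import numpy as np
import pytest

from redialab.datamodel import Colony, RediaRecord, Section, SizeClass
from redialab.morphometrics import enrich_colony


def make_colony(
    colony_id="C1",
    small_rel_pharynx=(),
    large_rel_pharynx=(),
    medium="water",
):
    """Colony with hand-set size classes and relative pharynx values.

    Length/width are chosen so the record validates; relative pharynx values
    are injected directly to make rank-sum inputs explicit.
    """
    from redialab.datamodel import Medium

    colony = Colony(colony_id=colony_id, dissection_medium=Medium(medium))
    i = 0
    for cls, values in (
        (SizeClass.SMALL, small_rel_pharynx),
        (SizeClass.LARGE, large_rel_pharynx),
    ):
        for v in values:
            i += 1
            r = RediaRecord(
                redia_id=f"{colony_id}-r{i}",
                colony_id=colony_id,
                section=Section.UNKNOWN,
                length_um=100.0,
                width_um=20.0,
            )
            r.size_class = cls
            r.relative_pharynx = v
            r.pharynx_volume_um3 = None if v is None else v * 31415.93
            colony.records.append(r)
    return colony


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simulated_colony():
    from redialab.simulate import ColonySimConfig, simulate_colony

    colony, truth = simulate_colony(ColonySimConfig(seed=7))
    return enrich_colony(colony), truth
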