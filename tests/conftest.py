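import numpy as np
import pandas as pd
import pytest

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass

from piosphere.community import SurveyDesign, TrapTable


def make_records(rows):
    return pd.DataFrame(
        rows,
        columns=["transect", "distance_m", "sample_point", "trap", "season",
                 "species", "count"],
    )


@pytest.fixture
def design():
    return SurveyDesign()


@pytest.fixture
def tiny_table(design):
    """Two traps in one sample point, two species, wet season only."""
    rows = [
        (1, 0, 1, 1, "wet", "spA", 3),
        (1, 0, 1, 2, "wet", "spA", 5),
        (1, 0, 1, 1, "wet", "spB", 2),
        (1, 50, 1, 1, "wet", "spA", 2),
    ]
    return TrapTable(make_records(rows), design)


@pytest.fixture
def two_season_table(design):
    rows = [
        (1, 0, 1, 1, "wet", "spA", 1),
        (1, 0, 1, 2, "wet", "spA", 3),
        (1, 50, 1, 1, "wet", "spA", 2),
        (1, 0, 1, 1, "dry", "spB", 4),
        (1, 50, 1, 1, "dry", "spB", 1),
    ]
    return TrapTable(make_records(rows), design)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
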