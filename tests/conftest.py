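import numpy as np
import pandas as pd
import pytest

from adslkit.behavior import HADSL, WT


def events_frame(rows):
    """Build a visit-event frame from (cage, day, timestamp, animal, corner, licks)."""
    return pd.DataFrame(
        rows, columns=["cage", "day", "timestamp", "animal", "corner", "licks"]
    )


def roster_frame(rows):
    return pd.DataFrame(rows, columns=["animal", "genotype", "sex", "cage"])


@pytest.fixture
def small_roster():
    """One cage, 2 hAdsl + 2 WT females."""
    return roster_frame(
        [
            ("h1", HADSL, "F", "c1"),
            ("h2", HADSL, "F", "c1"),
            ("w1", WT, "F", "c1"),
            ("w2", WT, "F", "c1"),
        ]
    )


@pytest.fixture
def alternating_events():
    """10 visits on one day strictly alternating hAdsl / WT."""
    animals = ["h1", "w1", "h2", "w2"] * 3
    return events_frame(
        [("c1", 1, 10.0 * i, animals[i], 1, 5) for i in range(10)]
    )
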