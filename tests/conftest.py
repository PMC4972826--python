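import numpy as np
import pandas as pd
import pytest

import colonynet as cn


def make_events(rows, roster=None):
    """Build an EventLog from (day, winner, loser, behavior, viv, zone) tuples."""
    df = pd.DataFrame(
        rows, columns=["day", "winner", "loser", "behavior", "vivarium", "zone"]
    )
    return cn.EventLog(df, roster=roster)


def freq_from_array(a, roster=None):
    a = np.asarray(a)
    roster = roster or [chr(ord("A") + i) for i in range(a.shape[0])]
    return pd.DataFrame(a, index=roster, columns=roster)


def transitive_tournament(n):
    """Binary matrix of a perfectly linear order 0 > 1 > ... > n-1."""
    b = np.triu(np.ones((n, n), dtype=int), 1)
    return freq_from_array(b)


@pytest.fixture(scope="session")
def colony():
    """One deterministic synthetic colony in the default (study) regime."""
    return cn.simulate_colony(cn.SimConfig(seed=42))


@pytest.fixture(scope="session")
def colony_freq(colony):
    return cn.build_frequency_matrix(colony.events)


@pytest.fixture(scope="session")
def colony_binary(colony_freq):
    return cn.binarize(colony_freq)
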