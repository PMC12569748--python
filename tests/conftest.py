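"""Shared fixtures and small random-data generators for the test suite."""

import numpy as np
import pandas as pd
import pytest

from cgrfs.data import CENSORED, MultistateDataset, toy_table1
from cgrfs.model import PROG6


@pytest.fixture
def toy():
    return toy_table1()


def random_prog6_dataset(rng, n, tie_times=True, censor_prob=0.35):
    """Random small progressive six-state dataset with integer event times.

    Integer times deliberately produce ties across individuals (a case the
    continuous-time simulator almost surely never generates).
    """
    prog_death = {0: (1, 5), 1: (2, 5), 2: (3, 5), 3: (4, 5), 4: (5, 5)}
    rows = []
    for i in range(n):
        state, t = 0, 0
        while state != 5:
            t += int(rng.integers(1, 6)) if tie_times else float(rng.exponential(5))
            if rng.random() < censor_prob:
                rows.append((i, state, CENSORED, t))
                break
            nxt, dead = prog_death[state]
            to = dead if rng.random() < 0.45 else nxt
            rows.append((i, state, to, t))
            state = to
    frame = pd.DataFrame(rows, columns=["id", "from", "to", "time"])
    return MultistateDataset(PROG6, frame)


def pure_survival_dataset(rng, n, hazard=0.01, cens_rate=0.005):
    """Dataset with only 0 -> 5 transitions (ordinary survival reduction)."""
    death = rng.exponential(1.0 / hazard, n)
    cens = rng.exponential(1.0 / cens_rate, n)
    rows = []
    for i in range(n):
        if death[i] <= cens[i]:
            rows.append((i, 0, 5, death[i]))
        else:
            rows.append((i, 0, CENSORED, cens[i]))
    frame = pd.DataFrame(rows, columns=["id", "from", "to", "time"])
    return MultistateDataset(PROG6, frame)


def uncensored_prog6_dataset(rng, n):
    return random_prog6_dataset(rng, n, censor_prob=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
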