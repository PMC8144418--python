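import itertools

import numpy as np
import pytest

from embryotx.estimation import TransferRecord
from embryotx.model import Cycle, EmbryoCategory, Stage


def enumerate_outcome_distribution(lbrs, uni):
    """Brute-force oracle for the transfer outcome distribution.

    Enumerates the favorable/unfavorable branch times every per-embryo
    birth pattern and sums path probabilities, independently of the
    package's dynamic-programming implementation.
    """
    n = len(lbrs)
    probs = np.zeros(n + 1)
    probs[0] += 1.0 - uni  # unfavorable branch: no births possible
    for pattern in itertools.product([0, 1], repeat=n):
        p = uni
        for born, lbr in zip(pattern, lbrs):
            q = lbr / uni
            p *= q if born else (1.0 - q)
        probs[sum(pattern)] += p
    return probs


@pytest.fixture
def brute_force_distribution():
    return enumerate_outcome_distribution


FRESH_BLAST = EmbryoCategory(Stage.BLASTOCYST, Cycle.FRESH)
FRESH_CLEAV = EmbryoCategory(Stage.CLEAVAGE, Cycle.FRESH)
FROZEN_BLAST = EmbryoCategory(Stage.BLASTOCYST, Cycle.FROZEN)
FROZEN_CLEAV = EmbryoCategory(Stage.CLEAVAGE, Cycle.FROZEN)


@pytest.fixture
def fresh_blast():
    return FRESH_BLAST


def make_record(n_embryos, n_births, age=30, category=FRESH_BLAST):
    return TransferRecord(
        age_at_retrieval=age,
        category=category,
        n_embryos=n_embryos,
        n_live_births=n_births,
    )


@pytest.fixture
def record_factory():
    return make_record
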