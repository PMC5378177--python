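import numpy as np
import pytest

from nucpos.model import AlignedProfile, Anchor
from nucpos.pipeline import simulate_cohort
from nucpos.synthetic import SimulationConfig


def make_profile(values, mask=None, lo=0, anchor=Anchor.ATG):
    """Small helper: wrap a vector as an AlignedProfile starting at offset lo."""
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.size, dtype=bool)
    return AlignedProfile(
        anchor=anchor, lo=lo, hi=lo + values.size - 1, values=values, mask=np.asarray(mask, bool)
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A compact two-condition cohort shared by read-only tests."""
    return simulate_cohort(SimulationConfig(seed=7, n_genes=120))


@pytest.fixture(scope="session")
def flat_cohort():
    """Two conditions with identical architecture (no planted differences)."""
    return simulate_cohort(
        SimulationConfig(
            seed=11,
            n_genes=80,
            nrl_by_condition={"wt": 170.0, "mut": 170.0},
            altered_condition="mut",
            remodeled_fraction=0.0,
        ),
        with_naked=False,
    )
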