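import numpy as np
import pytest

from linetester.anova import lt_anova
from linetester.simulate import TrialSimConfig, simulate_trial
from linetester.study_io import entry_means


@pytest.fixture(scope="session")
def small_trial():
    """A (4, 3, 3) trial with moderate genetic structure."""
    cfg = TrialSimConfig(l=4, t=3, r=3, mu=50.0, var_gca_line=4.0,
                         var_gca_tester=4.0, var_sca=6.0, var_rep=0.5,
                         var_error=1.0, parent_inbreeding_effect=5.0, seed=42)
    return simulate_trial(cfg)


@pytest.fixture(scope="session")
def full_trial():
    """A study-sized (20, 6, 3) trial with 4 checks."""
    cfg = TrialSimConfig(check_count=4, seed=7)
    return simulate_trial(cfg)


@pytest.fixture(scope="session")
def full_trial_analysis(full_trial):
    design, records, truth = full_trial
    anova = lt_anova(records, design, "y")
    cross_means = entry_means([r for r in records if r.role == "cross"], "y")
    parent_means = entry_means(
        [r for r in records if r.role in ("line_parent", "tester_parent")], "y"
    )
    return design, records, truth, anova, cross_means, parent_means


def rng_values(seed, shape, low=1.0, high=100.0):
    return np.random.default_rng(seed).uniform(low, high, size=shape)
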