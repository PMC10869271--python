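import numpy as np
import pytest

from phagekit.host_range import PanelStrain, SusceptibilityMatrix


def make_bool_matrix(calls, agents=None, strains=None, ancestors=None, outcomes=None):
    """Wrap a (n_reps, n_strains, n_agents) or (n_strains, n_agents) boolean
    array into a fully-present SusceptibilityMatrix."""
    calls = np.asarray(calls, dtype=bool)
    if calls.ndim == 2:
        calls = calls[np.newaxis]
    n_r, n_s, n_a = calls.shape
    if agents is None:
        agents = [f"cap{j + 1}" for j in range(n_a)]
    if strains is None:
        strains = [PanelStrain(strain_id=f"b{i + 1:03d}") for i in range(n_s)]
    return SusceptibilityMatrix(
        strains=strains,
        agents=agents,
        calls=calls,
        present=np.ones_like(calls, dtype=bool),
        outcomes=outcomes,
        ancestors=dict(ancestors) if ancestors else {},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
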