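import numpy as np
import pytest

from fairplay import ModelParams, Population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


#: Small, fast parameter set for unit tests of the dynamics.
@pytest.fixture
def small_params():
    return ModelParams(
        K=60, G=6, f=12, g=6, j=5, alpha=2, l=30, sd_l=5.0,
        T=20.0, d=3, P=0.5, r=0.01, R=10.0, p=0.3, c=0.0,
        F0=0.5, n_init_groups=3, n_init_per_group=8,
        init_resource_range=(5.0, 15.0), init_age_range=(5, 20),
        tau=200, burn_in=50,
    )


_AGENT_DEFAULTS = dict(
    parent_uid=-1, group=0, gene=False, adult=True, age=100,
    lifespan=1000, resources=0.0, bouts=0, is_fair=False,
    ever_played=False, last_repro=-10_000, birth_step=-1,
)


def make_population(params: ModelParams, agents: list[dict]) -> Population:
    """Build a Population with explicitly specified agents (test helper)."""
    pop = Population(params)
    cols = {k: [] for k in _AGENT_DEFAULTS}
    for spec in agents:
        unknown = set(spec) - set(_AGENT_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown agent fields: {unknown}")
        for k, default in _AGENT_DEFAULTS.items():
            cols[k].append(spec.get(k, default))
    pop.append(**cols)
    pop.next_group_id = int(max(cols["group"], default=-1)) + 1
    return pop
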