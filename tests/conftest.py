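import pytest

from supercut.synthdata import (
    ProfileRecipe,
    fig1_profile,
    fig2_profile,
    random_profile,
)


@pytest.fixture(scope="session")
def fig1():
    return fig1_profile()


@pytest.fixture(scope="session")
def fig2():
    return fig2_profile()


def small_random_profiles(n, **kw):
    """Seeded small profiles (profile, ground_truth) for sweep-style tests."""
    defaults = dict(n_labels=5, n_trees=2, subset_size=4, contraction_prob=0.2)
    defaults.update(kw)
    out = []
    for seed in range(n):
        out.append(random_profile(ProfileRecipe(seed=seed, **defaults)))
    return out
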