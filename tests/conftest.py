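import numpy as np
import pytest

import premls
from premls import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_balanced_windows():
    """A small all-category window set with clear per-type determinants."""
    spec = synthetic.SyntheticSpec(
        category_counts=(12,) * 11,
        signal_motifs={
            cat: tuple(
                synthetic.TYPE_MOTIFS[m] for m in sorted(premls.CATEGORY_MODS[cat])
            )
            for cat in range(1, 12)
        },
        seed=7,
    )
    return synthetic.generate(spec)


@pytest.fixture(scope="session")
def fitted_toy_model(tiny_balanced_windows):
    return premls.fit_propensity(
        premls.group_contexts_by_category(tiny_balanced_windows)
    )
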