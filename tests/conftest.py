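import numpy as np
import pytest

from mscformer import NetworkConfig, SynthSpec, TrainConfig, generate, make_worked_fixture


@pytest.fixture(scope="session")
def worked_fixture():
    return make_worked_fixture()


@pytest.fixture(scope="session")
def tiny_net_cfg():
    """Small network used by training-path tests (fast on one CPU)."""
    return NetworkConfig(
        channels=6, samples=250, n_classes=2, f1=4, heads=2, ff_dim=48,
        pool=25, depth=1,
    )


@pytest.fixture(scope="session")
def tiny_train_cfg():
    return TrainConfig(epochs=50, batch_size=48, seed=0)


def synth_pair(effect_size: float, n_per_class: int = 30):
    """Matched train/test synthetic sets at a given class effect size."""
    base = dict(
        n_trials_per_class=n_per_class, n_classes=2, channels=6, samples=250,
        effect_size=effect_size,
    )
    return (
        generate(SynthSpec(seed=11, **base)),
        generate(SynthSpec(seed=99, **base)),
    )


@pytest.fixture(scope="session")
def easy_synth_pair():
    return synth_pair(2.0)
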