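import numpy as np
import pytest
from hypothesis import settings

import evifuse as ev

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from evifuse.windowing import WindowConfig, WindowSet, slide_windows


@pytest.fixture(scope="session")
def frame2():
    return ev.ActivityFrame(2)


@pytest.fixture(scope="session")
def frame6():
    return ev.ActivityFrame(6)


def random_bpa(rng, frame, powerset=False):
    """A random valid BPA: dense over the powerset or over singletons+frame."""
    if powerset:
        elements = list(range(1, 2**frame.n))
    else:
        elements = [frame.singleton(i) for i in range(1, frame.n + 1)] + [frame.theta]
    w = rng.dirichlet(np.ones(len(elements)))
    return ev.BPA(frame, dict(zip(elements, w)))


@pytest.fixture(scope="session")
def separable_windows():
    """Windows from a two-activity, clearly separable synthetic recording:
    a walking-like oscillation vs a static posture."""
    profiles = [
        ev.ActivityProfile("walk", (0.0,) * 6, dynamic=True, amplitude=1.0,
                           frequency=2.0, noise_sd=0.2),
        ev.ActivityProfile("sit", (0.6, 0.2, 0.8, 0.0, 0.0, 0.0), noise_sd=0.2),
    ]
    rng = np.random.default_rng(0)
    schedule = [(int(a), 4.0) for a in rng.integers(1, 3, 30)]
    signal = ev.generate_signals(profiles, schedule, seed=1)
    return slide_windows(signal, WindowConfig(length=20, overlap=0.5))


@pytest.fixture(scope="session")
def trained_bank2(separable_windows, frame2):
    """A small bank trained on the separable two-activity windows, with a
    held-out test split."""
    ws = separable_windows
    test_mask = np.arange(ws.n_windows) % 5 == 0
    train = WindowSet(ws.windows[~test_mask], ws.labels[~test_mask], ws.step)
    test = WindowSet(ws.windows[test_mask], ws.labels[test_mask], ws.step)
    specs = [ev.SubnetworkSpec(6, 6, 6, 3)] * 2
    bank = ev.train_subnetwork_bank(
        train, frame2, specs, learning_rate=0.3, batch_size=128, epochs=30,
        seed=0, standardize=True,
    )
    return bank, train, test
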