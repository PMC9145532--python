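import numpy as np
import pytest

import wormalign as wa


@pytest.fixture()
def rng():
    # fresh per test: results do not depend on test execution order
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def straight_fixture():
    """Straight-tube worm: (mask, raw labeled cloud, ground-truth canonical)."""
    spec = wa.WormSpec(bend_angle=0.0, n_neurons=120, length=600.0)
    return wa.synth_worm(spec, seed=11)


@pytest.fixture(scope="session")
def bent_fixture():
    """Moderately bent worm fixture."""
    spec = wa.WormSpec(bend_angle=1.8, n_neurons=150, length=600.0)
    return wa.synth_worm(spec, seed=21)


@pytest.fixture(scope="session")
def bent_chain(bent_fixture):
    mask, _, _ = bent_fixture
    contour = wa.extract_boundary(mask)
    edges = wa.split_boundary(contour)
    return edges, wa.inscribe_circles(edges, n_circles=200)


@pytest.fixture(scope="session")
def substrate302():
    """A 302-neuron canonical substrate cloud carrying the full name list."""
    spec = wa.WormSpec(n_neurons=302)
    _, _, truth = wa.synth_worm(
        spec, seed=7, names=wa.neuron_name_list(exclude_can=False)
    )
    return truth


def random_cloud(rng, n, labeled=True, colored=False, frame="raw"):
    pos = rng.uniform([-50, -50, -20], [250, 50, 20], size=(n, 3))
    names = [f"N{i:03d}" for i in range(n)] if labeled else None
    colors = rng.integers(0, 3, size=n) if colored else None
    return wa.NeuronPointCloud(pos, names, colors, frame=frame)
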