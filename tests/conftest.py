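import numpy as np
import pytest

from shellmetrics import PhantomSpec, make_turtle_phantom


@pytest.fixture(scope="session")
def small_phantom_spec():
    """A compact phantom that keeps rotation/standardization tests fast."""
    return dict(
        canvas=(240, 320),
        center=(120.0, 160.0),
        body_axes=(120.0, 80.0),
        head_size=20.0,
        limb_size=10.0,
        tail_size=12.0,
    )


@pytest.fixture(scope="session")
def phantom_at(small_phantom_spec):
    cache = {}

    def make(heading, **overrides):
        key = (heading, tuple(sorted(overrides.items())))
        if key not in cache:
            cache[key] = make_turtle_phantom(
                PhantomSpec(heading=heading, **{**small_phantom_spec, **overrides})
            )
        return cache[key]

    return make


def mask_f1(pred, truth):
    p = pred == 255
    t = truth == 255
    tp = np.logical_and(p, t).sum()
    return 2 * tp / (p.sum() + t.sum())
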