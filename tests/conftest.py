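import warnings

import numpy as np
import pytest

from coameter import PhantomSpec, generate_cross_section


def phantom_battery(n: int, seed: int = 0, width: int = 181):
    """Deterministic battery of disc/ellipse phantoms, a third of them with
    intensity noise and one-pixel edge softening ("noisy edges")."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        a = float(rng.uniform(18, 70))
        b = a if i % 2 == 0 else float(rng.uniform(15, a))
        rot = float(rng.uniform(0, 180))
        noisy = i % 3 == 0
        spec = PhantomSpec(
            shape="disc" if i % 2 == 0 else "ellipse",
            a=a,
            b=b,
            rotation=rot,
            width=width,
            height=width,
            seed=seed + i,
            noise_sd=8.0 if noisy else 0.0,
            edge_sigma=0.5 if noisy else 0.0,
        )
        img, truth = generate_cross_section(spec)
        out.append((spec, img, truth))
    return out


@pytest.fixture(scope="session")
def small_battery():
    return phantom_battery(24)


@pytest.fixture(autouse=True)
def _quiet_centroid_warnings():
    # centroid-coincident contour points are routinely excluded on symmetric
    # phantoms; the warning is asserted explicitly where it matters
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*coincident with the centroid.*")
        yield
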