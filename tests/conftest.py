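import numpy as np
import pytest

from paddyid import geometry as geo
from paddyid import synthetic as syn


def random_seed_spec(rng: np.random.Generator) -> syn.SyntheticSeedSpec:
    """A silhouette spec drawn over the realistic single-seed parameter range."""
    return syn.SyntheticSeedSpec(
        body_semi_major=float(rng.uniform(135, 170)),
        body_semi_minor=float(rng.uniform(48, 64)),
        tip_length=float(rng.uniform(18, 34)),
        tip_width=float(rng.uniform(22, 38)),
        notch_depth_K=float(rng.uniform(6, 13)),
        notch_depth_L=float(rng.uniform(4, 9)),
        notch_angle=float(rng.uniform(4, 9)),
        rotation=float(rng.uniform(0, 360)),
    )


@pytest.fixture(scope="session")
def default_silhouette():
    """The default synthetic seed mask with its ground-truth record."""
    return syn.make_silhouette(syn.SyntheticSeedSpec())


@pytest.fixture(scope="session")
def default_geometry(default_silhouette):
    mask, _ = default_silhouette
    return geo.build_seed_geometry(mask)


@pytest.fixture(scope="session")
def small_population():
    """40 labeled feature vectors per variety (shared across classifier tests)."""
    rng = np.random.default_rng(2024)
    parts = [syn.sample_population(v, 40, rng) for v in syn.default_varieties()]
    X = np.vstack([p.features for p in parts])
    y = np.array(sum((p.labels for p in parts), []))
    return X, y


def ellipse_mask(a: int, b: int, pad: int = 4) -> np.ndarray:
    """Digitized axis-aligned ellipse with semi-axes a (cols) and b (rows)."""
    rr, cc = np.mgrid[-b - pad : b + pad + 1, -a - pad : a + pad + 1]
    return (cc / a) ** 2 + (rr / b) ** 2 <= 1.0
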