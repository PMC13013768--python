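import numpy as np
import pytest

from specaug.io_manifest import seeded_rng, spawn_rng
from specaug.synthetic_data import PhantomConfig, generate_phantom, generate_phantom_set


@pytest.fixture
def rng():
    return seeded_rng(12345)


@pytest.fixture(scope="session")
def phantom_cfg():
    """Small, fast phantom configuration shared across tests."""
    return PhantomConfig(n_images=10, image_size=96, seed=7)


@pytest.fixture(scope="session")
def phantoms(phantom_cfg):
    """In-memory phantoms: list of (image, sample, planted SR mask)."""
    return [
        generate_phantom(phantom_cfg, i, spawn_rng(phantom_cfg.seed, i))
        for i in range(phantom_cfg.n_images)
    ]


@pytest.fixture(scope="session")
def phantom_dir(tmp_path_factory, phantom_cfg):
    """Phantom set written to disk with its manifest."""
    out = tmp_path_factory.mktemp("phantoms")
    manifest = generate_phantom_set(phantom_cfg, out)
    return out, manifest


def brute_force_dilate(mask: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Independent double-loop dilation oracle, anchor at (kh//2, kw//2)."""
    h, w = mask.shape
    ay, ax = kh // 2, kw // 2
    out = np.zeros_like(mask, dtype=bool)
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            for i in range(kh):
                for j in range(kw):
                    ny, nx = y + i - ay, x + j - ax
                    if 0 <= ny < h and 0 <= nx < w:
                        out[ny, nx] = True
    return out
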