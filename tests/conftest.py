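import numpy as np
import pytest

from dilitracer import EncoderConfig, SimConfig, STViT, generate_sample, preprocess_stack
from dilitracer.stvit_model import CLASS_ORDER


@pytest.fixture(scope="session")
def sim_cfg():
    """Desk-scale simulator frame (dynamics identical to the defaults)."""
    return SimConfig().scaled(64)


@pytest.fixture(scope="session")
def sample_stacks(sim_cfg):
    """One generated stack per class, keyed by class index."""
    return {i: generate_sample(lab, sim_cfg, seed=11 + i) for i, lab in enumerate(CLASS_ORDER)}


@pytest.fixture(scope="session")
def tiny_model():
    return STViT(EncoderConfig.tiny(image_size=64), seed=0)


@pytest.fixture(scope="session")
def preprocessed(sample_stacks):
    return {i: preprocess_stack(s, out_size=64) for i, s in sample_stacks.items()}


def flood_fill_count(mask, min_size=4):
    """Independent connected-component counter (8-neighbour BFS)."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    count = 0
    for sy, sx in zip(*np.nonzero(mask)):
        if seen[sy, sx]:
            continue
        stack, size = [(sy, sx)], 0
        seen[sy, sx] = True
        while stack:
            y, x = stack.pop()
            size += 1
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < mask.shape[0] and 0 <= nx < mask.shape[1]:
                        if mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
        if size >= min_size:
            count += 1
    return count
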