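import numpy as np
import pytest

import scaffoldquant as sq


@pytest.fixture(scope="session")
def clean_pore_field():
    """Noise-free non-overlapping pore field with its ground truth."""
    spec = sq.PoreFieldSpec(n_pores=25, noise_sd=0.0, allow_overlap=False, seed=11)
    img, truth = sq.gen_pore_field(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def vertical_stripes():
    return sq.gen_channel_field(sq.ChannelFieldSpec(stripe_angle_deg=90.0, seed=0))


def flood_fill_label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Brute-force BFS labeling oracle, independent of the library path."""
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    h, w = mask.shape
    out = np.zeros((h, w), dtype=int)
    label = 0
    for r in range(h):
        for c in range(w):
            if mask[r, c] and out[r, c] == 0:
                label += 1
                stack = [(r, c)]
                out[r, c] = label
                while stack:
                    rr, cc = stack.pop()
                    for dr, dc in steps:
                        nr, nc = rr + dr, cc + dc
                        if (0 <= nr < h and 0 <= nc < w and mask[nr, nc]
                                and out[nr, nc] == 0):
                            out[nr, nc] = label
                            stack.append((nr, nc))
    return out


def label_sets(labels: np.ndarray) -> set[frozenset]:
    """Connected components as sets of pixel coordinates (label-order free)."""
    return {
        frozenset(zip(*np.nonzero(labels == k)))
        for k in range(1, labels.max() + 1)
    }
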