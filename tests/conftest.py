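import numpy as np
import pytest

import usjoint as uj


@pytest.fixture(scope="session")
def desk_spec() -> uj.PhantomSpec:
    """Small phantom geometry used throughout the suite: 64 px at 1 mm/px."""
    return uj.PhantomSpec(image_size=64, pixel_spacing=1.0)


@pytest.fixture(scope="session")
def eight_records(desk_spec) -> list[uj.LesionRecord]:
    """Two phantoms per class, fixed seeds."""
    return [uj.generate_phantom(desk_spec, label, seed)
            for label in uj.CLASS_NAMES for seed in (11, 12)]


@pytest.fixture(scope="session")
def tiny_net_config() -> uj.NetworkConfig:
    """A very small joint network for fast structural/gradient tests."""
    return uj.NetworkConfig(variant="joint", n_classes=4,
                            encoder_widths=(4, 6, 8, 8), fc_widths=(8,))


def brute_force_distance_map(clicks, shape, fill=255.0):
    """Double-loop oracle: min Euclidean distance of each pixel to any click."""
    h, w = shape
    out = np.full(shape, fill)
    for r in range(h):
        for c in range(w):
            best = fill
            for click in clicks:
                d = np.hypot(r - click.row, c - click.col)
                best = min(best, d)
            out[r, c] = best
    return out
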