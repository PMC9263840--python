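"""Shared deterministic fixtures for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from perirad.features.texture import DiscretizedRoi


def random_droi(seed: int, max_side: int = 6, max_levels: int = 5
                ) -> DiscretizedRoi:
    """Random small discretized ROI for oracle comparisons."""
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(3, max_side + 1, size=3))
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    n_levels = int(rng.integers(2, max_levels + 1))
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    observed = int(levels.max())
    intensities = (levels[mask] - 0.5) * 25.0
    return DiscretizedRoi(levels=levels, mask=mask, bin_width=25.0,
                          n_levels=observed, intensities=intensities)


@pytest.fixture(scope="session")
def small_case():
    """One deterministic phantom case at reduced grid."""
    from perirad import ImageParams, default_profiles, generate_case
    params = ImageParams(shape=(48, 48, 24), spacing=(0.9, 0.9, 2.0),
                         tumor_semiaxis_range_mm=(5.0, 7.0))
    return generate_case(default_profiles()[0], params, seed=123,
                         case_id="t_0001", with_resegmentation=True)
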