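"""Shared fixtures: the study phantom and its fitted transform.

Session-scoped because the phantom build (~5 s) and the CDT fit (~4 s)
are the expensive steps; every test reads them immutably.
"""

import math
import warnings

import numpy as np
import pytest

import straightax as sx


@pytest.fixture(scope="session")
def bundle():
    """Default study phantom: 96^3 grid, half-turn curl, 25 landmarks."""
    return sx.make_phantom(sx.default_config(seed=0))


@pytest.fixture(scope="session")
def transform(bundle):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sx.fit_cdt(bundle.landmarks, bundle.curved_mask, bundle.straight_mask)


@pytest.fixture(scope="session")
def fields(transform):
    return sx.curved_axis_fields(transform)


@pytest.fixture(scope="session")
def bundle_quarter():
    """Quarter-turn phantom: fold-free at the default landmark density."""
    return sx.make_phantom(sx.default_config(seed=0, curl_angle=math.pi / 2))


@pytest.fixture(scope="session")
def transform_quarter(bundle_quarter):
    b = bundle_quarter
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sx.fit_cdt(b.landmarks, b.curved_mask, b.straight_mask)


@pytest.fixture(scope="session")
def identity_bundle():
    """Zero-curvature phantom: curved and straight spaces coincide."""
    return sx.make_phantom(sx.default_config(seed=0, curl_angle=0.0))


def tube_mask(shape=(12, 12, 24), radius=4.0, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    """Small axis-aligned cylinder mask for cheap transform tests."""
    idx = np.indices(shape, dtype=float)
    cx, cy = (shape[0] - 1) / 2, (shape[1] - 1) / 2
    m = ((idx[0] - cx) ** 2 + (idx[1] - cy) ** 2) <= radius**2
    return sx.Volume(m.astype(np.uint8), spacing, origin)


def c_mask(n=24, thickness=2):
    """A C-shaped slab: geodesics must go the long way around the gap."""
    m = np.zeros((n, n, thickness), dtype=np.uint8)
    c = (n - 1) / 2
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    r = np.sqrt((ii - c) ** 2 + (jj - c) ** 2)
    ring = (r >= n * 0.28) & (r <= n * 0.45)
    gap = (jj > c) & (np.abs(ii - c) < n * 0.12)
    for k in range(thickness):
        m[:, :, k] = (ring & ~gap).astype(np.uint8)
    return sx.Volume(m)
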