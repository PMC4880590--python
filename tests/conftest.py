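"""Shared fixtures: the worked-example data and one reusable rendered scan."""

import numpy as np
import pandas as pd
import pytest

from leafspad import calibration, synthetic
from leafspad.containers import SegmentTable
from leafspad.datasets import REFERENCE_SPAD_PARTS, reference_profile


@pytest.fixture(scope="session")
def reference_spad():
    """Per-part SPAD values of the worked-example blade, base to tip."""
    return REFERENCE_SPAD_PARTS.copy()


@pytest.fixture(scope="session")
def ref_profile():
    """The worked-example quadratic chlorophyll profile."""
    return reference_profile()


@pytest.fixture(scope="session")
def rendered():
    """One noise-free 300-dpi synthetic scan with its generating truth.

    Session-scoped: the render is the most expensive fixture and every
    scan-processing test can share it read-only.
    """
    shape = synthetic.make_leaf_shape(25.0, 1.2, 0.45, 201)
    profile = synthetic.make_profile(25.0, 33.8, 40.8, 0.55)
    config = synthetic.GeneratorConfig(seed=3, noise_sd_dn=0.0, dpi=300)
    scan = synthetic.render_leaf_scan(
        shape, profile, calibration.published_model(), config)
    return {"scan": scan, "shape": shape, "profile": profile, "config": config}


def make_table(spad_values, areas=None):
    """Build a minimal SegmentTable for diagnostics tests."""
    spad = np.asarray(spad_values, dtype=float)
    k = spad.size
    if areas is None:
        areas = np.ones(k)
    return SegmentTable(pd.DataFrame({
        "part": np.arange(1, k + 1),
        "area_cm2": areas,
        "dn_r": np.full(k, 100.0),
        "dn_g": np.full(k, 165.0),
        "dn_b": np.full(k, 20.0),
        "spad": spad,
        "pixel_count": np.full(k, 1000),
    }))
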