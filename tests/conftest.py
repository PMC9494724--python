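"""Shared fixtures: small synthetic datasets reused across the suite.

Desk-scale raster maps (10×10 spots) keep preprocessing and training fast
while preserving the structure of the full 51×51 scans.
"""

from __future__ import annotations

import numpy as np
import pytest

import ramantissue as rt
from ramantissue.preprocess import preprocess_ml_batch


DATASET_SEED = 5


def _make_dataset(noise_sigma: float, n_maps_per_class: int = 3):
    cfg = rt.SimulationConfig(n_rows=10, n_cols=10, seed=DATASET_SEED)
    maps, manifest = rt.simulate_dataset(
        n_maps_per_class=n_maps_per_class, cfg=cfg, noise_sigma=noise_sigma)
    return maps, manifest


@pytest.fixture(scope="session")
def dataset_default():
    """12 labelled maps (3 per class, 3 patients) at the default noise level."""
    return _make_dataset(noise_sigma=0.05)


@pytest.fixture(scope="session")
def dataset_quiet():
    """Same layout as dataset_default but with zero detector noise."""
    return _make_dataset(noise_sigma=0.0)


def _featureset(maps):
    feats_1d, feats_2d, labels, groups = [], [], [], []
    for m in maps:
        f1 = preprocess_ml_batch(m.grid, m.flat_intensities(), mode="1d")
        f2 = preprocess_ml_batch(m.grid, m.flat_intensities(), mode="2d")
        feats_1d.extend(f1)
        feats_2d.extend(f2)
        labels.extend([m.meta.tissue_class] * len(f1))
        groups.extend([m.meta.map_id] * len(f1))
    return feats_1d, feats_2d, labels, groups


@pytest.fixture(scope="session")
def features_default():
    """Per-spot ML features (both modes) for one map per class, default noise."""
    maps, _ = _make_dataset(noise_sigma=0.05, n_maps_per_class=1)
    return _featureset(maps)


@pytest.fixture(scope="session")
def features_quiet():
    """Per-spot ML features (both modes) for one map per class, zero noise."""
    maps, _ = _make_dataset(noise_sigma=0.0, n_maps_per_class=1)
    return _featureset(maps)


@pytest.fixture()
def tiny_spectrum():
    wn = np.arange(400.0, 420.0)
    return rt.Spectrum(wn, np.linspace(0.0, 1.0, len(wn)))
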