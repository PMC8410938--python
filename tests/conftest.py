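"""Shared fixtures: small, fast synthetic configurations and helpers."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from widevolt.preprocessing import bin_spatial, preprocess
from widevolt.registration import RegionTrace, make_vessel_mask, rasterize_atlas, region_trace
from widevolt.synthetic import (
    Optics,
    SyntheticConfig,
    forepaw_config,
    generate_voltage_truth,
    render_trial,
)


def make_trace(
    values, frame_rate: float = 100.0, stim_indices=(124,), region: str = "S1FL", n_pixels: int = 100
) -> RegionTrace:
    """Build a RegionTrace from raw values (0-based stimulus indices)."""
    return RegionTrace(
        region=region,
        drr=np.asarray(values, dtype=float),
        frame_rate=frame_rate,
        stim_indices=tuple(stim_indices),
        n_pixels=n_pixels,
    )


@pytest.fixture(scope="session")
def fast_cfg() -> SyntheticConfig:
    """Forepaw condition at 10x reduced sensor (120x192 raw, 30x48 binned)."""
    return forepaw_config(scale=10)


@pytest.fixture(scope="session")
def fast_truth(fast_cfg):
    return generate_voltage_truth(fast_cfg)


@pytest.fixture(scope="session")
def fast_seq(fast_cfg, fast_truth):
    return render_trial(fast_truth, fast_cfg, seed=7)


@pytest.fixture(scope="session")
def fast_ratio(fast_cfg, fast_seq):
    lit = bin_spatial(fast_seq.donor[74].astype(float), fast_cfg.bin_factor)
    vessel = make_vessel_mask(lit, method="otsu")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ratio, prov = preprocess(fast_seq, vessel_mask=vessel)
    return ratio, prov


@pytest.fixture(scope="session")
def fast_labels(fast_cfg, fast_ratio):
    ratio, _ = fast_ratio
    return rasterize_atlas(fast_cfg.layout(), ratio.drr.shape[1:])


def noiseless_config(scale: int = 10, **kwargs) -> SyntheticConfig:
    kwargs.setdefault("optics", Optics(noise_sd_counts=0.0))
    return forepaw_config(scale=scale, **kwargs)
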