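"""Shared fixtures: shape masks and (cached) synthetic fields."""

from __future__ import annotations

import numpy as np
import pytest

from gliaquant.synthetic import (
    CultureParams,
    generate_field,
    high_snr_params,
)


def make_disk(radius: int, pad: int = 3) -> np.ndarray:
    n = 2 * radius + 1 + 2 * pad
    yy, xx = np.mgrid[:n, :n] - n // 2
    return (yy * yy + xx * xx) <= radius * radius


def make_rect(h: int, w: int, pad: int = 3) -> np.ndarray:
    return np.pad(np.ones((h, w), dtype=bool), pad)


def make_rot_rect(w: float, h: float, deg: float, n: int | None = None) -> np.ndarray:
    """Rasterized rectangle of continuous size w x h rotated by ``deg``."""
    n = n or int(np.ceil(np.hypot(w, h))) + 8
    yy, xx = np.mgrid[:n, :n]
    c = (n - 1) / 2
    th = np.deg2rad(deg)
    u = np.cos(th) * (xx - c) + np.sin(th) * (yy - c)
    v = -np.sin(th) * (xx - c) + np.cos(th) * (yy - c)
    return (np.abs(u) <= w / 2) & (np.abs(v) <= h / 2)


def make_ellipse(a: float, b: float, deg: float = 0.0) -> np.ndarray:
    n = int(2 * max(a, b)) + 9
    yy, xx = np.mgrid[:n, :n]
    c = (n - 1) / 2
    th = np.deg2rad(deg)
    u = np.cos(th) * (xx - c) + np.sin(th) * (yy - c)
    v = -np.sin(th) * (xx - c) + np.cos(th) * (yy - c)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


@pytest.fixture(scope="session")
def noise_free_field():
    """One vehicle-like field with noise and illumination disabled."""
    params = CultureParams(
        seed=101, noise=(0.0, 0.0), illumination_gradient_amplitude=0.0
    )
    return generate_field(params) + (params,)


@pytest.fixture(scope="session")
def high_snr_field():
    params = high_snr_params(seed=202)
    return generate_field(params) + (params,)


@pytest.fixture(scope="session")
def default_noise_field():
    params = CultureParams(seed=303)
    return generate_field(params) + (params,)


@pytest.fixture(scope="session")
def high_snr_fixture_set():
    """The default high-SNR validation set: 20 fields, fixed seeds."""
    out = []
    for i in range(20):
        params = high_snr_params(seed=7000 + i)
        fimg, truth = generate_field(params, field_id=f"f{i:02d}")
        out.append((fimg, truth))
    return out
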