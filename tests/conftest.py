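"""Shared fixtures: tiny phantoms and synthetic pixel series.

All fixtures are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

import relaxmap as rm


@pytest.fixture(scope="session")
def settings():
    return rm.FitSettings()


def make_pixel(model_id, variant="3p", tau=1000.0, A=100.0, B=None, times=None,
               sigma=0.0, seed=0):
    """Noiseless (or Gaussian-noisy) single-pixel series for one model.

    For MOLLI models ``tau`` is the apparent T1*.  Returns (values, times,
    model).
    """
    model = rm.get_model(model_id, variant)
    if B is None:
        B = model.ideal_b
    if times is None:
        times = rm.default_times(model_id)
    times = np.asarray(times, dtype=float)
    params = rm.ModelParams(A=A, B=B, tau=tau)
    values = rm.predict_signal(model, params, times)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, sigma, values.shape)
        if not model.signed:
            values = np.abs(values)
    return np.asarray(values, dtype=float), times, model


@pytest.fixture(scope="session")
def small_sr_phantom():
    """Noiseless 12-vial SR-bSSFP phantom, small enough for fast map fits."""
    spec = rm.default_eurospin_spec(shape=(36, 48), model_id="sr_bssfp", variant="3p")
    series, truth = rm.simulate_series(spec)
    return spec, series, truth
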