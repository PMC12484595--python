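"""Synthetic echo-integration grids with known vertical-distribution truth.

Each time bin holds a Gaussian-in-depth scattering layer whose mean and
variance may be perturbed as a linear function of source distance (the
planted "response").  Cells get multiplicative lognormal noise.  The
returned ground truth carries the continuous-limit center of mass (the
layer mean) and inertia (the layer variance) per time bin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..echo import SvGrid, linear_to_db
from .scenarios import LayerScenario

__all__ = ["gen_echogram"]

_LN10_OVER_10 = np.log(10.0) / 10.0


def gen_echogram(scenario: LayerScenario, track: pd.DataFrame):
    """Simulate an Sv grid over the track's time span.

    Returns ``(SvGrid, truth)`` where ``truth`` has per-time-bin columns
    ``time_s, distance_m, cm_true_m, inertia_true_m2``.  Raises if the
    perturbed layer escapes the observable water column.
    """
    dz, dt = scenario.grid_dz, scenario.grid_dt
    z_max = scenario.water_depth - scenario.transducer_clearance
    depth_centers = np.arange(dz / 2.0, z_max, dz)
    t0, t1 = float(track["time_s"].min()), float(track["time_s"].max())
    time_centers = np.arange(t0 + dt / 2.0, t1, dt)
    if time_centers.size == 0 or depth_centers.size == 0:
        raise ValueError("track span or water column too small for the grid")

    dist = np.interp(time_centers, track["time_s"], track["distance_m"])
    d_km = dist / 1000.0
    means = np.array([scenario.mean_at(t) for t in time_centers])
    sds = np.array([scenario.sd_at(t) for t in time_centers])
    means = means + scenario.response.cm_slope_m_per_km * d_km
    variances = sds ** 2 + scenario.response.inertia_slope_m2_per_km * d_km
    if np.any(variances <= 0):
        raise ValueError("planted inertia response drives layer variance ≤ 0")
    if np.any(means <= 0) or np.any(means >= scenario.water_depth):
        raise ValueError("layer mean escapes the water column")

    peak = 10.0 ** (scenario.layer_strength / 10.0)
    zz = depth_centers[:, None]
    sv = peak * np.exp(-((zz - means[None, :]) ** 2) / (2.0 * variances[None, :]))
    if scenario.noise_sd_db > 0:
        rng = np.random.default_rng(scenario.seed)
        sigma_ln = scenario.noise_sd_db * _LN10_OVER_10
        sv = sv * np.exp(rng.normal(0.0, sigma_ln, size=sv.shape))

    grid = SvGrid(linear_to_db(sv), depth_centers, time_centers)
    truth = pd.DataFrame({
        "time_s": time_centers,
        "distance_m": dist,
        "cm_true_m": means,
        "inertia_true_m2": variances,
    })
    return grid, truth
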