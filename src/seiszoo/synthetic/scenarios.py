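"""Scenario definitions for the synthetic field-study generators.

Each scenario is a frozen bundle of the parameters one stage of the study
design needs, with defaults set to the field conditions the pipeline is
meant to emulate: a seismic vessel approaching a stationary observation
station at 4.5 knots firing every ~10.7 s over a ~10 km line, a 158 dB re
1 µPa²s broadband vessel-noise floor per 10 s window, a Gaussian zooplankton
layer in a ~70 m water column observed on a 2 m × 2 s echo-integration grid,
a bag exposure experiment with the field design's arm sizes (bags of 10: 12
control / 18 handling control / 9 far / 36 close), and back-lit photographs
of red-stained organisms.  Seeds are explicit fields; there is no global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "KNOTS_TO_MS",
    "ApproachScenario",
    "LayerResponse",
    "LayerScenario",
    "TreatmentArm",
    "MortalityScenario",
    "ImageScenario",
    "hazard_for_day7_target",
    "default_mortality_scenario",
]

KNOTS_TO_MS = 0.514444  # 1 knot in m/s; 4.5 knots ≈ 2.315 m/s


@dataclass(frozen=True)
class ApproachScenario:
    """Seismic vessel approach and airgun firing schedule.

    ``source_sel_at_1m`` with ``spreading_exponent`` = 20 (spherical
    spreading, 20·log10 r transmission loss) sets the per-shot received SEL;
    the default 233 dB re 1 µPa²s puts the shot level at the 158 dB noise
    floor near 6 km from the source.  ``noise_floor_sel`` is the expected
    broadband SEL of a 10 s noise-only window.
    """

    start_distance: float = 10_000.0      # m
    vessel_speed: float = 4.5 * KNOTS_TO_MS  # m/s
    shot_interval: float = 10.7           # s
    source_sel_at_1m: float = 233.0       # dB re 1 µPa²s at 1 m
    noise_floor_sel: float = 158.0        # dB re 1 µPa²s per 10 s window
    spreading_exponent: float = 20.0
    sample_rate: float = 48_000.0         # Hz
    duration: float | None = None         # s; None = full approach to the pass
    seed: int = 0

    def __post_init__(self):
        if self.start_distance <= 0:
            raise ValueError("start_distance must be positive")
        if self.vessel_speed <= 0:
            raise ValueError("vessel_speed must be positive")
        if self.shot_interval <= 0:
            raise ValueError("shot_interval must be positive")
        if self.sample_rate < 40_000:
            raise ValueError("sample_rate must be ≥ 40 kHz to cover the "
                             "10 Hz – 20 kHz analysis band")

    @property
    def approach_time(self) -> float:
        """Time for the source to reach the station, s."""
        return self.start_distance / self.vessel_speed

    @property
    def effective_duration(self) -> float:
        return self.approach_time if self.duration is None else self.duration


@dataclass(frozen=True)
class LayerResponse:
    """Distance-dependent perturbation planted into the scattering layer.

    Slopes are per km of distance FROM the source: a positive
    ``inertia_slope_m2_per_km`` makes the layer variance grow with distance,
    the qualitative pattern of a layer that is more dispersed far from the
    disturbance observation point.
    """

    cm_slope_m_per_km: float = 0.0
    inertia_slope_m2_per_km: float = 0.0


@dataclass(frozen=True)
class LayerScenario:
    """Gaussian zooplankton scattering layer in a flat-bottom water column.

    ``layer_mean_depth`` / ``layer_sd`` may be constants or callables of
    time (s) to emulate diel-migration ramps.  ``layer_strength`` is the Sv
    at the layer core.  The upward-looking transducer sits 5 m above the
    seafloor, so the observable depth range is [0, water_depth − 5] m.
    Multiplicative lognormal cell noise has a dB-domain standard deviation
    ``noise_sd_db``.
    """

    water_depth: float = 70.0              # m
    layer_mean_depth: float | Callable[[float], float] = 25.0
    layer_sd: float | Callable[[float], float] = 5.0
    layer_strength: float = -75.0          # dB re 1 m⁻¹ at layer core
    noise_sd_db: float = 3.0
    grid_dt: float = 2.0                   # s
    grid_dz: float = 2.0                   # m
    surface_exclusion: float = 5.0         # m
    transducer_clearance: float = 5.0      # m above seafloor
    response: LayerResponse = field(default_factory=LayerResponse)
    seed: int = 0

    def __post_init__(self):
        if self.grid_dz <= 0 or self.grid_dt <= 0:
            raise ValueError("grid_dz and grid_dt must be positive")
        if self.water_depth <= 0:
            raise ValueError("water_depth must be positive")

    def mean_at(self, t: float) -> float:
        m = self.layer_mean_depth
        return float(m(t)) if callable(m) else float(m)

    def sd_at(self, t: float) -> float:
        s = self.layer_sd
        s = float(s(t)) if callable(s) else float(s)
        if s <= 0:
            raise ValueError("layer_sd must be positive")
        return s


@dataclass(frozen=True)
class TreatmentArm:
    """One treatment arm of the bag experiment.

    Mortality is a two-stage process: immediate deaths at day 0 with
    probability ``day0_death_prob`` per individual, then a constant daily
    hazard ``daily_hazard`` for each survivor (geometric survival, matching
    daily inspection).
    """

    name: str
    n_bags: int
    n_individuals: int
    day0_death_prob: float
    daily_hazard: float

    def __post_init__(self):
        if self.n_bags < 1 or self.n_individuals < 1:
            raise ValueError("n_bags and n_individuals must be ≥ 1")
        for p in (self.day0_death_prob, self.daily_hazard):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def expected_cumulative(self, day: int) -> float:
        """Closed-form expected cumulative proportion dead at ``day``:
        1 − (1 − p0)(1 − h)^day."""
        return 1.0 - (1.0 - self.day0_death_prob) * (1.0 - self.daily_hazard) ** day


def hazard_for_day7_target(day0_death_prob: float, day7_total: float,
                           days: int = 7) -> float:
    """Daily hazard that makes expected cumulative mortality hit
    ``day7_total`` at day ``days`` given the day-0 probability."""
    if not 0 <= day0_death_prob <= day7_total < 1:
        raise ValueError("need 0 ≤ day0 ≤ day7 target < 1")
    return 1.0 - ((1.0 - day7_total) / (1.0 - day0_death_prob)) ** (1.0 / days)


def _flat_curve(level: float):
    return lambda distance_m: level


@dataclass(frozen=True)
class MortalityScenario:
    """Bag-experiment arms plus the net-haul mortality field.

    ``net_mortality_curve`` maps distance (m) to the expected dead fraction
    of a haul; ``net_dispersion`` is the beta-binomial intra-class
    correlation reproducing between-haul overdispersion (0 = pure binomial).
    """

    treatments: Sequence[TreatmentArm]
    follow_up_days: int = 7
    net_mortality_curve: Callable[[float], float] = field(
        default_factory=lambda: _flat_curve(0.15))
    net_dispersion: float = 0.05
    net_haul_size: int = 100
    seed: int = 0

    def __post_init__(self):
        if not self.treatments:
            raise ValueError("need at least one treatment arm")
        if self.follow_up_days < 0:
            raise ValueError("follow_up_days must be non-negative")
        if not 0.0 <= self.net_dispersion < 1.0:
            raise ValueError("net_dispersion must be in [0, 1)")

    def arm(self, name: str) -> TreatmentArm:
        for t in self.treatments:
            if t.name == name:
                return t
        raise KeyError(name)


def default_mortality_scenario(seed: int = 0) -> MortalityScenario:
    """The bag design this generator emulates, for bags of 10 individuals.

    Arm sizes are 12 control, 18 handling control, 9 far exposure and 36
    close exposure bags.  Day-0 probabilities follow the immediate
    mortalities observed in the field (close 5.4%, far 2.3%; controls set to
    2%, between the far arm and zero) and daily hazards are solved so the
    expected day-7 cumulative mortalities equal the observed
    12.7 / 11.7 / 22.3 / 25.1%.
    """
    arms = [
        ("control", 12, 0.020, 0.127),
        ("handling_control", 18, 0.020, 0.117),
        ("exposure_far", 9, 0.023, 0.223),
        ("exposure_close", 36, 0.054, 0.251),
    ]
    treatments = [
        TreatmentArm(name, n_bags, 10, p0, hazard_for_day7_target(p0, day7))
        for name, n_bags, p0, day7 in arms
    ]
    return MortalityScenario(treatments=treatments, seed=seed)


@dataclass(frozen=True)
class ImageScenario:
    """Synthetic back-lit photograph of stained organisms.

    Live and dead organisms differ in red-channel saturation: the live
    distribution must stochastically exceed the dead one.  Organisms are
    ellipses placed without overlap on a light background; pixel noise is
    i.i.d. Gaussian in 8-bit units.
    """

    n_organisms: int = 40
    live_fraction: float = 0.5
    canvas: tuple[int, int] = (512, 512)
    organism_size_px: tuple[int, int] = (8, 16)   # semi-axis range
    live_stain_intensity: tuple[float, float] = (0.75, 0.06)  # saturation mean, sd
    dead_stain_intensity: tuple[float, float] = (0.15, 0.05)
    background_level: int = 235
    noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.live_fraction <= 1.0:
            raise ValueError("live_fraction must be in [0, 1]")
        if self.n_organisms < 0:
            raise ValueError("n_organisms must be non-negative")
        if self.live_stain_intensity[0] <= self.dead_stain_intensity[0]:
            raise ValueError("live stain intensity must exceed dead stain intensity")
        if self.organism_size_px[0] < 2:
            raise ValueError("organisms must be at least 2 px")
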