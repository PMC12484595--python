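"""Synthetic bag experiments and net hauls with known mortality processes.

Bag mortality is a two-stage process per individual: death at day 0 with
the arm's immediate probability, then a constant daily hazard for each
survivor (geometric survival — the closed-form expected cumulative
proportion dead at day d is 1 − (1 − p0)(1 − h)^d).  Net-haul dead counts
are beta-binomial around a distance-dependent mean to reproduce the
between-haul overdispersion seen in field data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .scenarios import MortalityScenario

__all__ = ["gen_bag_trials", "gen_net_samples"]


def gen_bag_trials(scenario: MortalityScenario, seed: int | None = None) -> pd.DataFrame:
    """Simulate every bag of the scenario; wide format.

    Columns: bag_id, treatment, line_id, n0, dead_day0..dead_day{D}.
    Cumulative dead counts are nondecreasing and bounded by n0 by
    construction.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    days = scenario.follow_up_days
    rows = []
    bag_no = 0
    for arm in scenario.treatments:
        for b in range(arm.n_bags):
            n = arm.n_individuals
            dead = int(rng.binomial(n, arm.day0_death_prob))
            cum = [dead]
            alive = n - dead
            for _ in range(days):
                new = int(rng.binomial(alive, arm.daily_hazard)) if alive else 0
                alive -= new
                cum.append(cum[-1] + new)
            row = {"bag_id": f"bag{bag_no:03d}", "treatment": arm.name,
                   "line_id": b // 3, "n0": n}
            row.update({f"dead_day{d}": cum[d] for d in range(days + 1)})
            rows.append(row)
            bag_no += 1
    return pd.DataFrame(rows)


def gen_net_samples(scenario: MortalityScenario, distances,
                    phases=None, approach: int = 1,
                    seed: int | None = None) -> pd.DataFrame:
    """Simulate WP2-net hauls at the given source distances (m).

    Dead counts are beta-binomial with mean ``net_mortality_curve(distance)``
    and intra-class correlation ``net_dispersion`` (binomial when zero).
    ``phases`` labels each haul 'during' or 'after'; default all 'during'.
    """
    distances = np.asarray(list(distances), dtype=float)
    if distances.size == 0:
        raise ValueError("distances must be non-empty")
    if phases is None:
        phases = ["during"] * distances.size
    if len(phases) != distances.size:
        raise ValueError("phases must match distances in length")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n = scenario.net_haul_size
    rho = scenario.net_dispersion
    rows = []
    for k, (d, ph) in enumerate(zip(distances, phases)):
        p = float(np.clip(scenario.net_mortality_curve(d), 0.0, 1.0))
        if rho > 0 and 0.0 < p < 1.0:
            conc = (1.0 - rho) / rho
            p_draw = rng.beta(p * conc, (1.0 - p) * conc)
        else:
            p_draw = p
        dead = int(rng.binomial(n, p_draw))
        rows.append({"haul_id": f"haul{k:03d}", "approach": approach,
                     "distance_m": float(d), "phase": ph,
                     "n_live": n - dead, "n_dead": dead})
    return pd.DataFrame(rows)
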