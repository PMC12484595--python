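"""Synthetic photographs of stained organisms with known live/dead labels.

Organisms are non-overlapping ellipses on a light back-lit background.
Live animals get a deep red body (high red-channel saturation drawn from
the live distribution); dead animals are pale gray-brown (low saturation
from the dead distribution).  Labels are returned for accuracy scoring of
the downstream classifier.
"""

from __future__ import annotations

import colorsys

import numpy as np
import pandas as pd
from skimage.draw import ellipse

from .scenarios import ImageScenario

__all__ = ["gen_stain_images", "gen_stain_image"]

_MAX_PLACEMENT_TRIES = 200
_BODY_VALUE = 0.55          # brightness of the organism body (dark on light)


def _place_organisms(scenario: ImageScenario, rng) -> list[tuple]:
    """Random non-overlapping (row, col, a, b, theta) placements."""
    h, w = scenario.canvas
    lo, hi = scenario.organism_size_px
    margin = hi + 4
    if h <= 2 * margin or w <= 2 * margin:
        raise ValueError("canvas too small for organism placement")
    placed: list[tuple] = []
    for _ in range(scenario.n_organisms):
        for attempt in range(_MAX_PLACEMENT_TRIES):
            r = rng.uniform(margin, h - margin)
            c = rng.uniform(margin, w - margin)
            a = rng.uniform(lo, hi)
            b = rng.uniform(lo, hi) * 0.6
            if all((r - r2) ** 2 + (c - c2) ** 2 > (2.2 * hi) ** 2
                   for r2, c2, *_ in placed):
                placed.append((r, c, a, b, rng.uniform(0, np.pi)))
                break
        else:
            raise RuntimeError(
                f"could not place organism {len(placed)} without overlap "
                f"after {_MAX_PLACEMENT_TRIES} tries")
    return placed


def gen_stain_image(scenario: ImageScenario, seed: int | None = None):
    """One synthetic photograph; returns ``(rgb uint8 array, labels)``.

    ``labels`` columns: organism_id, row, col, area_px (approximate),
    status ('live'/'dead'), saturation.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    h, w = scenario.canvas
    img = np.full((h, w, 3), float(scenario.background_level))
    placements = _place_organisms(scenario, rng)
    n_live = int(round(scenario.live_fraction * len(placements)))
    statuses = ["live"] * n_live + ["dead"] * (len(placements) - n_live)
    rng.shuffle(statuses)

    rows = []
    for k, ((r, c, a, b, theta), status) in enumerate(zip(placements, statuses)):
        mean, sd = (scenario.live_stain_intensity if status == "live"
                    else scenario.dead_stain_intensity)
        sat = float(np.clip(rng.normal(mean, sd), 0.0, 1.0))
        rgb = colorsys.hsv_to_rgb(0.0, sat, _BODY_VALUE)  # hue 0 = red
        rr, cc = ellipse(r, c, a, b, shape=(h, w), rotation=theta)
        img[rr, cc] = np.array(rgb) * 255.0
        rows.append({"organism_id": k, "row": r, "col": c,
                     "area_px": int(rr.size), "status": status,
                     "saturation": sat})
    if scenario.noise_sd > 0:
        img += rng.normal(0.0, scenario.noise_sd, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    labels = pd.DataFrame(rows, columns=["organism_id", "row", "col",
                                         "area_px", "status", "saturation"])
    return img, labels


def gen_stain_images(scenario: ImageScenario, n_images: int = 1):
    """A batch of photographs: list of (image, labels) pairs, seeds derived
    deterministically from the scenario seed."""
    rng = np.random.default_rng(scenario.seed)
    return [gen_stain_image(scenario, seed=int(rng.integers(2 ** 31)))
            for _ in range(n_images)]
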