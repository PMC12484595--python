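"""Live/dead classification of Neutral-Red-stained plankton photographs.

Neutral Red is a vital stain: living zooplankton actively take it up and turn
deep red, while dead animals show only weak diffusive coloration.  Specimens
are photographed dark-on-light (back-lit Petri dishes).  The classifier is a
transparent two-step procedure:

1. segment organisms as dark connected components against the light
   background (automatic Otsu threshold, 8-connectivity, area bounds);
2. within each component, count pixels whose HSV color falls in a red hue
   window with sufficient saturation — the *stain fraction* — and call the
   animal live when that fraction reaches a configured minimum.

Hue/saturation thresholds make the call invariant to uniform brightness
changes.  Touching animals are deliberately not split; area outliers are
flagged instead so a human can audit the overlay image (stained pixels
painted vivid green, mirroring macro-marked audit images).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.color import rgb2gray, rgb2hsv
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "StainThresholds",
    "load_image",
    "segment_organisms",
    "stain_fraction",
    "classify",
    "analyze_image",
    "batch_vital_report",
    "overlay_stain",
]


@dataclass(frozen=True)
class StainThresholds:
    """Color-threshold configuration for the stain classifier.

    hue window is circular (degrees on the 0–360 hue axis, red wraps through
    zero); saturation/value are in [0, 1].  An organism is live when at least
    ``min_stain_fraction`` of its pixels pass the color test.  Area bounds
    (px) reject debris and merged clumps at segmentation time.
    """

    hue_lo_deg: float = 320.0
    hue_hi_deg: float = 40.0
    min_saturation: float = 0.35
    min_value: float = 0.10
    max_value: float = 0.95
    min_stain_fraction: float = 0.25
    min_area_px: int = 40
    max_area_px: int = 50_000

    def __post_init__(self):
        if not 0.0 <= self.min_stain_fraction <= 1.0:
            raise ValueError("min_stain_fraction must be in [0, 1]")
        if self.hue_lo_deg % 360.0 == self.hue_hi_deg % 360.0:
            raise ValueError("hue window is empty")

    def to_dict(self) -> dict:
        return asdict(self)


def load_image(path) -> np.ndarray:
    """Read PNG/TIFF as an RGB uint8 array (alpha dropped)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def _as_rgb_float(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("expected an RGB image (H, W, 3)")
    img = img[..., :3]
    if img.dtype == np.uint8:
        return img / 255.0
    return np.clip(img.astype(float), 0.0, 1.0)


def _stain_mask(image: np.ndarray, thresholds: StainThresholds) -> np.ndarray:
    """Boolean mask of pixels inside the red hue/saturation/value window."""
    hsv = rgb2hsv(_as_rgb_float(image))
    hue = hsv[..., 0] * 360.0
    lo, hi = thresholds.hue_lo_deg % 360.0, thresholds.hue_hi_deg % 360.0
    if lo <= hi:
        in_hue = (hue >= lo) & (hue <= hi)
    else:  # wraps through 0° (the red band)
        in_hue = (hue >= lo) | (hue <= hi)
    return (in_hue
            & (hsv[..., 1] >= thresholds.min_saturation)
            & (hsv[..., 2] >= thresholds.min_value)
            & (hsv[..., 2] <= thresholds.max_value))


def segment_organisms(image: np.ndarray, thresholds: StainThresholds = StainThresholds()):
    """Connected dark regions within the configured area bounds.

    Foreground is everything darker than the automatic (Otsu) background
    threshold of the grayscale image; components touching each other merge
    (no watershed splitting).  Returns a list of ``skimage`` region
    properties; empty for a blank image.
    """
    gray = rgb2gray(_as_rgb_float(image))
    if np.ptp(gray) < 1e-6:
        return []
    fg = gray < threshold_otsu(gray)
    if not fg.any():
        return []
    lab = label(fg, connectivity=2)
    return [r for r in regionprops(lab)
            if thresholds.min_area_px <= r.area <= thresholds.max_area_px]


def stain_fraction(image: np.ndarray, region, thresholds: StainThresholds) -> float:
    """Fraction of a region's pixels inside the red stain window."""
    coords = region.coords if hasattr(region, "coords") else np.asarray(region)
    if len(coords) == 0:
        raise ValueError("empty region")
    mask = _stain_mask(image, thresholds)
    return float(mask[coords[:, 0], coords[:, 1]].mean())


def classify(fraction: float, thresholds: StainThresholds) -> str:
    """'live' iff stain fraction ≥ min_stain_fraction (boundary counts live)."""
    return "live" if fraction >= thresholds.min_stain_fraction else "dead"


def analyze_image(image: np.ndarray,
                  thresholds: StainThresholds = StainThresholds(),
                  image_id: str = "") -> pd.DataFrame:
    """Detections for one photograph: area, stain fraction, vital status."""
    regions = segment_organisms(image, thresholds)
    rows = []
    for k, r in enumerate(regions):
        frac = stain_fraction(image, r, thresholds)
        rows.append({
            "image": image_id,
            "object_id": k,
            "area_px": int(r.area),
            "centroid_row": float(r.centroid[0]),
            "centroid_col": float(r.centroid[1]),
            "stain_fraction": frac,
            "status": classify(frac, thresholds),
        })
    return pd.DataFrame(rows, columns=["image", "object_id", "area_px",
                                       "centroid_row", "centroid_col",
                                       "stain_fraction", "status"])


def batch_vital_report(images, thresholds: StainThresholds = StainThresholds()):
    """Per-image live/dead counts plus pooled proportion dead.

    ``images`` maps image ids to RGB arrays or file paths.  Unreadable images
    are collected in the returned error list instead of aborting the batch.

    Returns
    -------
    report : DataFrame with image, n_live, n_dead, proportion_dead
    detections : DataFrame of every detection
    errors : list of (image id, message)
    """
    if isinstance(images, (list, tuple)):
        images = {str(i): im for i, im in enumerate(images)}
    if not images:
        raise ValueError("need at least one image")
    per_image, dets, errors = [], [], []
    for name, im in images.items():
        try:
            arr = load_image(im) if isinstance(im, (str, Path)) else im
            det = analyze_image(arr, thresholds, image_id=name)
        except Exception as exc:  # unreadable/corrupt file: report, keep going
            errors.append((name, str(exc)))
            continue
        dets.append(det)
        n_live = int((det["status"] == "live").sum())
        n_dead = int((det["status"] == "dead").sum())
        total = n_live + n_dead
        per_image.append({"image": name, "n_live": n_live, "n_dead": n_dead,
                          "proportion_dead": n_dead / total if total else np.nan})
    report = pd.DataFrame(per_image, columns=["image", "n_live", "n_dead",
                                              "proportion_dead"])
    detections = (pd.concat(dets, ignore_index=True) if dets
                  else analyze_image(np.full((4, 4, 3), 255, np.uint8), thresholds))
    if len(report):
        n_live, n_dead = report["n_live"].sum(), report["n_dead"].sum()
        pooled = pd.DataFrame([{"image": "__pooled__", "n_live": n_live,
                                "n_dead": n_dead,
                                "proportion_dead": n_dead / (n_live + n_dead)
                                if n_live + n_dead else np.nan}])
        report = pd.concat([report, pooled], ignore_index=True)
    return report, detections, errors


def overlay_stain(image: np.ndarray, thresholds: StainThresholds = StainThresholds(),
                  color=(0, 255, 0)) -> np.ndarray:
    """Audit image with stain-window pixels painted a vivid green."""
    img = np.asarray(image)
    out = (img.copy() if img.dtype == np.uint8
           else (np.clip(img, 0, 1) * 255).astype(np.uint8))
    out[_stain_mask(image, thresholds)] = color
    return out
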