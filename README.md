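# seiszoo

Tools for quantifying the exposure of zooplankton to seismic-airgun surveys
and the biological responses that exposure may produce.  The package is
aimed at marine-bioacoustics and zooplankton-ecology groups who run field
experiments in which a seismic vessel approaches a stationary observation
station: a hydrophone records the received sound, an upward-looking
echosounder watches the scattering layer, plankton nets and bag exposures
measure mortality, and Neutral-Red-stained photographs separate live from
dead animals.

Every analysis stage is paired with a synthetic-data generator that
reproduces the statistical structure of those designs, so the whole chain
can be validated against known ground truth without any field data.

## What it computes

**Sound metrics** (`seiszoo.hydroacoustics`).  Calibrated pressure p(t) in
Pa from raw hydrophone WAVs; per-window broadband sound exposure level and
peak-to-peak pressure in the 10 Hz–20 kHz band over contiguous 10 s
windows, joined to the distance of the source:

    SEL = 10 log₁₀( ∫ p² dt / (p_ref² t_ref) )  dB re 1 µPa²s,  p_ref = 1 µPa
    p2p = max p − min p                          (Pa)

**Vertical-distribution indicators** (`seiszoo.echo`).  From a depth × time
grid of volume backscattering strength Sv (dB re 1 m⁻¹), computed in the
linear domain sv = 10^(Sv/10):

    CM  = Σ z·sv·Δz / Σ sv·Δz          center of mass (m)
    I   = Σ (z−CM)²·sv·Δz / Σ sv·Δz    inertia (m²)
    s_A = 4π·1852²·Σ sv·Δz             area scattering (m² nmi⁻²)

plus surface/bottom exclusion masks, distance binning, and an OLS model of
each indicator against source distance (`IndicatorDistanceModel.fit()`).

**Live/dead image classification** (`seiszoo.staining`).  Neutral Red is a
vital stain: live zooplankton turn deep red, dead ones stay pale.  Organisms
are segmented as dark connected components on the back-lit background, the
fraction of each body's pixels inside a red HSV window is measured, and a
configurable stain-fraction threshold calls live vs dead, with a vivid-green
overlay image for auditing.

**Mortality statistics** (`seiszoo.mortality`).  Spearman correlation of
net-haul proportion dead vs distance and Mann-Whitney during-vs-after
comparison (both with exact permutation p-values at small n), per-treatment
cumulative mortality curves, and a binomial GLM of bag mortality
(`proportion ~ treatment * day`, bag size as binomial weight) exposed as
`BagMortalityModel` → `fit()` → results with `summary()`, Wald contrasts, a
likelihood-ratio test of all treatment terms, and a Monte-Carlo
`power_analysis`.

## Worked example

One command simulates a full study (vessel approach at 4.5 knots firing
every 10.7 s against a 158 dB re 1 µPa²s noise floor; a Gaussian layer at
25 m ± 5 m in a 70 m column on a 2 m × 2 s grid with a planted +2 m²/km
inertia response; the four-arm bag experiment; stained photographs) and
re-analyzes it:

```python
from seiszoo.pipeline import run_all

report = run_all(overrides={"seed": 7}, outdir="demo_run")
print(report["headline"])
```

```
{'cm_slope_significant': False, 'inertia_slope_significant': True,
 'inertia_slope_positive': True, 'cumulative_treatment_significant': True,
 'immediate_treatment_significant': False}
```

i.e. the run reproduces the expected qualitative pattern: no center-of-mass
trend with distance (p = 0.22), a significant positive inertia trend
(slope 0.0020 m² per m ≈ 2.0 m² per km, matching the planted response), a
significant cumulative bag-mortality treatment effect (likelihood-ratio
p ≈ 7·10⁻¹⁵) but no significant immediate effect (p = 0.21).  Stage detail
from the same run:

```
sound:  max SEL 159.2 dB re 1 µPa²s, max p2p 848 Pa, 6×10 s windows
echo:   mean CM 25.01 m (truth 25.00), mean inertia 34.76 m² (truth 35.00)
images: proportion dead 0.500 (truth 0.500)
nets:   Spearman rho 0.122, p 0.617 (n = 19 hauls during exposure)
```

`demo_run/` then contains the dataset (`data/*.csv`), per-stage tables and
`report.json` / `report.md`.  The same stages are available as a CLI:

```bash
seiszoo simulate --seed 7 --out demo_run
seiszoo sound --wav demo_run/data/recording.wav --track demo_run/data/track.csv
seiszoo echo --grid demo_run/data/sv_grid.csv --track demo_run/data/track.csv
seiszoo mortality --nets demo_run/data/nets.csv --bags demo_run/data/bags.csv
seiszoo run-all --seed 7
```

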