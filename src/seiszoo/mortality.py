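"""Mortality statistics for net hauls and bag exposure experiments.

Four analyses mirror a standard seismic-exposure design:

* Spearman rank correlation of net-haul proportion dead against distance to
  the source (immediate field mortality vs exposure level);
* Mann-Whitney rank-sum comparison of hauls taken during vs after exposure;
* per-treatment cumulative-mortality curves (day 0..7 mean ± SD across bags);
* a binomial GLM of the proportion dead with treatment, day and their
  interaction as fixed effects, plus a day-0-only ("immediate") variant.

Rank tests use exact permutation enumeration at small sample sizes and
tie-corrected large-sample approximations otherwise.  The GLM is exposed
statsmodels-style: :class:`BagMortalityModel` with ``fit()`` returning
:class:`BagGlmResults`.

The repeated-measures structure of cumulative bag data (the same bag
contributes all eight days) is NOT modelled — the model is the plain GLM as
used in the field, and results objects carry the caveat in ``summary()``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "proportion_dead",
    "spearman_mortality_distance",
    "mann_whitney_during_after",
    "exact_spearman_p",
    "exact_mann_whitney",
    "cumulative_mortality_curve",
    "bags_to_long",
    "BagMortalityModel",
    "BagGlmResults",
    "fit_bag_glm",
    "power_analysis",
]

DAY_COLS = [f"dead_day{d}" for d in range(8)]


def proportion_dead(n_dead, n_total) -> float:
    """dead / total; errors on an empty denominator."""
    if np.any(np.asarray(n_total) <= 0):
        raise ValueError("total count must be positive")
    return np.asarray(n_dead, dtype=float) / np.asarray(n_total, dtype=float) \
        if np.ndim(n_dead) else float(n_dead) / float(n_total)


# ---------------------------------------------------------------------------
# rank tests with exact small-sample enumeration
# ---------------------------------------------------------------------------

_EXACT_SPEARMAN_N = 9          # 9! = 362 880 permutations, still fast
_EXACT_MW_TOTAL = 18           # C(18, 9) = 48 620 assignments


def _rank_corr(rx, ry) -> float:
    """Pearson correlation of two (mid-)rank vectors."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        return np.nan
    return float((rx * ry).sum() / denom)


def exact_spearman_p(x, y) -> tuple[float, float]:
    """Spearman rho with a two-sided exact permutation p-value.

    All n! orderings of the y-ranks are enumerated (mid-ranks, so ties are
    handled); p is the fraction of permutations with |rho| at least the
    observed |rho|.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rank_corr(rx, ry)
    if not np.isfinite(rho):
        return np.nan, np.nan
    perms = np.array(list(itertools.permutations(ry)))
    rxc = rx - rx.mean()
    pc = perms - ry.mean()
    denom = np.sqrt((rxc ** 2).sum() * ((ry - ry.mean()) ** 2).sum())
    rhos = pc @ rxc / denom
    p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    return rho, p


def spearman_mortality_distance(samples: pd.DataFrame,
                                phase: str | None = "during") -> dict:
    """Spearman correlation of proportion dead vs distance to the source.

    Exact permutation p for n ≤ 9, large-sample approximation otherwise.
    Constant mortality or constant distance leaves rho undefined: NaN is
    returned with a warning rather than an exception.
    """
    df = samples
    if phase is not None and "phase" in df.columns:
        df = df[df["phase"] == phase]
    if len(df) < 3:
        raise ValueError("need at least 3 samples")
    prop = df["n_dead"].to_numpy() / (df["n_dead"] + df["n_live"]).to_numpy()
    dist = df["distance_m"].to_numpy(dtype=float)
    if np.ptp(prop) == 0 or np.ptp(dist) == 0:
        warnings.warn("constant mortality or distance: Spearman rho undefined")
        return {"rho": np.nan, "p": np.nan, "n": len(df), "method": "undefined"}
    if len(df) <= _EXACT_SPEARMAN_N:
        rho, p = exact_spearman_p(dist, prop)
        return {"rho": rho, "p": p, "n": len(df), "method": "exact permutation"}
    rho, p = stats.spearmanr(dist, prop)
    return {"rho": float(rho), "p": float(p), "n": len(df),
            "method": "large-sample t approximation"}


def exact_mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U with a two-sided exact permutation p-value.

    Enumerates every assignment of the pooled values to the two groups
    (mid-ranks, tie-safe); the two-sided p is the probability of a U at
    least as far from its null mean n1·n2/2 as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    idx = np.array(list(itertools.combinations(range(n1 + n2), n1)))
    u_all = ranks[idx].sum(axis=1) - n1 * (n1 + 1) / 2.0
    p = float(np.mean(np.abs(u_all - mu) >= abs(u_obs - mu) - 1e-9))
    return float(u_obs), p


def mann_whitney_during_after(samples: pd.DataFrame) -> dict:
    """Two-sided rank-sum test of proportion dead, during vs after exposure.

    Exact enumeration for combined n ≤ 18, tie-corrected normal
    approximation otherwise.
    """
    prop = samples["n_dead"].to_numpy() / \
        (samples["n_dead"] + samples["n_live"]).to_numpy()
    during = prop[samples["phase"].to_numpy() == "during"]
    after = prop[samples["phase"].to_numpy() == "after"]
    if during.size == 0 or after.size == 0:
        raise ValueError("both phases must be non-empty")
    if during.size + after.size <= _EXACT_MW_TOTAL:
        u, p = exact_mann_whitney(during, after)
        method = "exact permutation"
    else:
        u, p = stats.mannwhitneyu(during, after, alternative="two-sided",
                                  method="asymptotic")
        u, p = float(u), float(p)
        method = "tie-corrected normal approximation"
    return {"U": u, "p": p, "n_during": int(during.size),
            "n_after": int(after.size), "method": method}


# ---------------------------------------------------------------------------
# bag experiments
# ---------------------------------------------------------------------------

def bags_to_long(trials: pd.DataFrame, days=range(8)) -> pd.DataFrame:
    """Wide bag table (dead_day0..dead_day7) → long bag-day rows.

    Output columns: bag_id, treatment, day, dead (cumulative), alive, n0,
    prop.  Validates that cumulative deaths are nondecreasing and ≤ n0.
    """
    rows = []
    for _, r in trials.iterrows():
        prev = -1
        for d in days:
            col = f"dead_day{d}"
            if col not in trials.columns:
                raise ValueError(f"day index {d} outside recorded follow-up")
            dead = int(r[col])
            if dead < prev:
                raise ValueError("cumulative dead counts must be nondecreasing")
            if dead > r["n0"]:
                raise ValueError("dead count exceeds bag size")
            prev = dead
            rows.append({"bag_id": r["bag_id"], "treatment": r["treatment"],
                         "day": int(d), "dead": dead,
                         "alive": int(r["n0"]) - dead, "n0": int(r["n0"]),
                         "prop": dead / r["n0"]})
    return pd.DataFrame(rows)


def cumulative_mortality_curve(trials: pd.DataFrame, treatment: str) -> pd.DataFrame:
    """Across-bag mean ± SD of cumulative proportion dead per day."""
    sub = trials[trials["treatment"] == treatment]
    if len(sub) == 0:
        raise ValueError(f"no bags with treatment {treatment!r}")
    long = bags_to_long(sub)
    g = long.groupby("day")["prop"]
    out = g.agg(mean="mean", sd="std", n_bags="size").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    out.insert(0, "treatment", treatment)
    return out


def _detect_separation(long: pd.DataFrame) -> list[str]:
    """Treatments whose pooled response is all-dead or all-alive."""
    bad = []
    for t, sub in long.groupby("treatment"):
        if sub["dead"].sum() == 0 or sub["alive"].sum() == 0:
            bad.append(str(t))
    return sorted(bad)


class BagMortalityModel:
    """Binomial GLM of bag mortality: ``proportion ~ treatment * day``.

    The response is the per-bag-day (dead, alive) count pair, encoded as a
    proportion with the bag size as variance weight — the faithful binomial
    weighting when bags of 10 and 50 are mixed.  Day enters as a continuous
    covariate by default (``day_as_factor=True`` switches to factor coding).
    ``immediate=True`` restricts to day 0 and drops the day terms — the
    immediate-mortality analysis.

    Complete separation (a treatment arm with no deaths, or no survivors) is
    detected up front; the fit then falls back to a continuity-corrected
    (add 0.5 dead and 0.5 alive per row) penalized fit, flagged on the
    results object.
    """

    def __init__(self, trials: pd.DataFrame, reference: str = "control",
                 include_interaction: bool = True, day_as_factor: bool = False,
                 immediate: bool = False):
        treatments = sorted(trials["treatment"].unique())
        if len(treatments) < 2:
            raise ValueError("need at least two treatments")
        if reference not in treatments:
            raise ValueError(f"reference level {reference!r} not among {treatments}")
        days = [0] if immediate else range(8)
        long = bags_to_long(trials, days=days)
        self.reference = reference
        self.immediate = immediate
        self.include_interaction = include_interaction and not immediate
        self.day_as_factor = day_as_factor
        self.data = long
        self.separated = _detect_separation(long)

        tr = f"C(treatment, Treatment({reference!r}))"
        day = "C(day)" if day_as_factor else "day"
        if immediate:
            rhs = tr
        elif self.include_interaction:
            rhs = f"{tr} * {day}"
        else:
            rhs = f"{tr} + {day}"
        self.formula = f"prop ~ {rhs}"
        self._rhs_reduced = "1" if immediate else day

    def _fit_formula(self, formula: str, data: pd.DataFrame):
        return smf.glm(formula, data=data, family=sm.families.Binomial(),
                       var_weights=data["n0"].to_numpy(dtype=float)).fit()

    def fit(self) -> "BagGlmResults":
        data = self.data
        penalized = False
        if self.separated:
            warnings.warn(
                "complete separation in treatment(s) "
                f"{self.separated}: using continuity-corrected penalized fit")
            data = data.copy()
            data["prop"] = (data["dead"] + 0.5) / (data["n0"] + 1.0)
            data["n0"] = data["n0"] + 1
            penalized = True
        res = self._fit_formula(self.formula, data)
        res_reduced = self._fit_formula(f"prop ~ {self._rhs_reduced}", data)
        return BagGlmResults(self, res, res_reduced, penalized)


@dataclass
class BagGlmResults:
    """Coefficient table plus treatment-effect tests for the bag GLM."""

    model: BagMortalityModel
    _res: object
    _res_no_treatment: object
    penalized: bool = False

    @property
    def params(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self._res.params,
            "se": self._res.bse,
            "p": self._res.pvalues,
        })

    @property
    def n(self) -> int:
        return int(self._res.nobs)

    def treatment_contrast(self, treatment: str) -> dict:
        """Wald test of one treatment's main-effect log-odds contrast vs the
        reference level (at day 0 when day is continuous with interaction)."""
        key = f"[T.{treatment}]"
        names = [c for c in self._res.params.index
                 if key in c and ":" not in c]
        if not names:
            raise KeyError(f"no main-effect coefficient for {treatment!r}")
        name = names[0]
        return {"treatment": treatment,
                "estimate": float(self._res.params[name]),
                "se": float(self._res.bse[name]),
                "p": float(self._res.pvalues[name])}

    @property
    def lrt_treatment(self) -> dict:
        """Likelihood-ratio test of ALL treatment terms (main effects and, if
        present, interactions) against the no-treatment model."""
        dev = float(self._res_no_treatment.deviance - self._res.deviance)
        df = int(self._res.df_model - self._res_no_treatment.df_model)
        p = float(stats.chi2.sf(dev, df)) if df > 0 else np.nan
        return {"statistic": dev, "df": df, "p": p}

    @property
    def separated_treatments(self) -> list[str]:
        return self.model.separated

    def summary(self) -> str:
        lines = [
            f"Binomial GLM: {self.model.formula}",
            f"n bag-days = {self.n}"
            + ("  [immediate, day 0 only]" if self.model.immediate else ""),
            self.params.to_string(float_format=lambda v: f"{v: .4f}"),
            "LRT (all treatment terms): G² = {statistic:.3f}, df = {df}, "
            "p = {p:.4g}".format(**self.lrt_treatment),
        ]
        if self.penalized:
            lines.append(f"WARNING: complete separation in {self.separated_treatments}; "
                         "continuity-corrected penalized fit")
        if not self.model.immediate:
            lines.append("note: within-bag correlation across days is not modelled")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"formula": self.model.formula, "n": self.n,
                "coefficients": {k: {"estimate": float(self._res.params[k]),
                                     "se": float(self._res.bse[k]),
                                     "p": float(self._res.pvalues[k])}
                                 for k in self._res.params.index},
                "lrt_treatment": self.lrt_treatment,
                "penalized": self.penalized,
                "separated_treatments": self.separated_treatments}


def fit_bag_glm(trials: pd.DataFrame, reference: str = "control",
                include_interaction: bool = True, day_as_factor: bool = False,
                immediate: bool = False) -> BagGlmResults:
    """Build and fit :class:`BagMortalityModel` in one call."""
    return BagMortalityModel(trials, reference=reference,
                             include_interaction=include_interaction,
                             day_as_factor=day_as_factor,
                             immediate=immediate).fit()


def power_analysis(scenario, n_reps: int = 200, alpha: float = 0.05,
                   contrast: str = "exposure_close", model: str = "cumulative",
                   use_lrt: bool = True, seed: int | None = None) -> dict:
    """Monte-Carlo power of the bag-GLM treatment test under a scenario.

    Simulates ``n_reps`` bag experiments from ``scenario`` (its own design —
    arm sizes, rates — is used as-is), fits the chosen model variant and
    counts rejections at ``alpha``.  ``use_lrt`` tests all treatment terms
    jointly; otherwise the Wald p of ``contrast`` vs the reference is used.
    Returns the power estimate with a normal-approximation 95% CI.
    """
    from .synthetic.mortality import gen_bag_trials

    if n_reps < 100:
        raise ValueError("n_reps must be at least 100 for a stable estimate")
    if all(t.day0_death_prob in (0.0, 1.0) and t.daily_hazard in (0.0, 1.0)
           for t in scenario.treatments):
        raise ValueError("degenerate scenario: no stochastic mortality")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    rejections = 0
    used = 0
    for _ in range(n_reps):
        trials = gen_bag_trials(scenario, seed=int(rng.integers(2 ** 31)))
        try:
            res = fit_bag_glm(trials, immediate=(model == "immediate"))
            p = res.lrt_treatment["p"] if use_lrt \
                else res.treatment_contrast(contrast)["p"]
        except Exception:
            continue
        used += 1
        if p < alpha:
            rejections += 1
    if used == 0:
        raise RuntimeError("no replicate could be fitted")
    power = rejections / used
    half = 1.96 * np.sqrt(power * (1 - power) / used)
    return {"power": power, "ci95": (max(0.0, power - half), min(1.0, power + half)),
            "n_reps": used, "alpha": alpha, "model": model,
            "test": "lrt" if use_lrt else f"wald:{contrast}"}
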