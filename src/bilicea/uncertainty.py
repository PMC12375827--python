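"""Deterministic, probabilistic and scenario uncertainty analysis.

One-way DSA reruns the model with each parameter pushed to its low and high
bound (±20% of base case by default) and orders parameters by the width of
the resulting ICER bar (tornado order).  PSA draws 5,000 joint parameter
vectors — gamma distributions for costs, beta for probabilities and
utilities, both moment-matched so each parameter's mean equals its base
value, plus (optionally) survival parameters from each fit's asymptotic
multivariate normal — and reruns the model per draw; the draws feed the
cost-effectiveness acceptability curve and the ICE-quadrant summary.
Scenario analysis rescans the model over a grid of pembrolizumab price
reductions and locates the smallest reduction that brings the ICER under a
willingness-to-pay threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AE_NAMES, CountryConfig, ModelSettings, apply_overrides
from .engine import CEAResult, run_cea
from .fitting import ParametricFit

__all__ = [
    "ParamRange",
    "ParamDist",
    "PSADraw",
    "CEACPoint",
    "CEAContext",
    "default_dsa_ranges",
    "one_way_dsa",
    "moments_to_gamma",
    "moments_to_beta",
    "psa_parameter_distributions",
    "run_psa",
    "ceac",
    "default_wtp_grid",
    "ice_quadrants",
    "scenario_price_grid",
    "price_threshold_for_wtp",
    "DEFAULT_PRICE_REDUCTIONS",
]

#: pembrolizumab price-reduction grid for scenario analysis (fractions)
DEFAULT_PRICE_REDUCTIONS = (0.10, 0.20, 0.30, 0.40, 0.50,
                            0.60, 0.70, 0.80, 0.90, 0.95)

#: ±20% of base case, treated as a 95% interval when deriving PSA spreads
DEFAULT_RELATIVE_RANGE = 0.20


# ---------------------------------------------------------------------------
# model context
# ---------------------------------------------------------------------------

@dataclass
class CEAContext:
    """Everything needed to rerun the economic model: the four selected
    survival fits, a country configuration and the cycle settings."""

    exp_fits: Mapping[str, ParametricFit]
    ctl_fits: Mapping[str, ParametricFit]
    config: CountryConfig
    settings: ModelSettings = field(default_factory=ModelSettings)

    def run(self, overrides: Mapping[str, float] | None = None,
            exp_fits: Mapping[str, ParametricFit] | None = None,
            ctl_fits: Mapping[str, ParametricFit] | None = None) -> CEAResult:
        config = apply_overrides(self.config, overrides) if overrides \
            else self.config
        return run_cea(exp_fits or self.exp_fits, ctl_fits or self.ctl_fits,
                       config, self.settings)

    def base_result(self) -> CEAResult:
        return self.run()


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamRange:
    """Base value and DSA bounds of one parameter."""

    param: str
    base: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.param}: need low <= base <= high")


def _iter_parameter_ids(config: CountryConfig):
    for drug in config.drug_prices:
        yield f"drug_price.{drug}", config.drug_prices[drug].usd_per_vial, False
    for ae in AE_NAMES:
        yield f"ae_cost.{ae}", config.ae_costs[ae], False
    for ae in AE_NAMES:
        yield f"ae_prob_pem.{ae}", config.ae_prob_pem[ae], True
    for ae in AE_NAMES:
        yield f"ae_prob_chem.{ae}", config.ae_prob_chem[ae], True
    for name in ("examination_cost", "administration_cost", "bsc_cost",
                 "eol_cost"):
        yield name, getattr(config, name), False
    for name in ("u_pfs", "u_pd"):
        yield name, getattr(config, name), True


def default_dsa_ranges(config: CountryConfig,
                       rel: float = DEFAULT_RELATIVE_RANGE
                       ) -> list[ParamRange]:
    """±``rel`` ranges around base case for every cost, probability and
    utility input (bounded parameters are capped at 1)."""
    out = []
    for param, base, bounded in _iter_parameter_ids(config):
        high = base * (1.0 + rel)
        if bounded:
            high = min(high, 1.0)
        out.append(ParamRange(param, base, base * (1.0 - rel), high))
    return out


def one_way_dsa(ranges: Sequence[ParamRange], ctx: CEAContext) -> pd.DataFrame:
    """Rerun the model at each parameter's low and high bound.

    Returns a DataFrame (parameter, base, low, high, icer_low, icer_high,
    width) sorted by descending bar width; a failed extreme run is recorded
    as NaN for that side rather than aborting the analysis.
    """
    rows = []
    for r in ranges:
        icers = {}
        for side, value in (("icer_low", r.low), ("icer_high", r.high)):
            try:
                res = ctx.run(overrides={r.param: value})
                icers[side] = res.icer if res.status == "icer" else math.nan
            except Exception:            # an extreme run may legitimately fail
                icers[side] = math.nan
        width = abs(icers["icer_high"] - icers["icer_low"]) \
            if all(np.isfinite(v) for v in icers.values()) else math.nan
        rows.append({"parameter": r.param, "base": r.base, "low": r.low,
                     "high": r.high, **icers, "width": width})
    frame = pd.DataFrame(rows)
    return frame.sort_values("width", ascending=False,
                             na_position="last").reset_index(drop=True)


# ---------------------------------------------------------------------------
# PSA parameter distributions
# ---------------------------------------------------------------------------

def moments_to_gamma(mean: float, sd: float) -> tuple[float, float]:
    """(shape, scale) of the gamma distribution with the given moments."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be > 0")
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return shape, scale


def moments_to_beta(mean: float, sd: float) -> tuple[float, float]:
    """(alpha, beta) of the beta distribution with the given moments."""
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must be in (0, 1)")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    if sd * sd >= mean * (1.0 - mean):
        raise ValueError("variance infeasible for beta")
    alpha = mean * (mean * (1.0 - mean) / (sd * sd) - 1.0)
    beta = alpha * (1.0 - mean) / mean
    return alpha, beta


@dataclass(frozen=True)
class ParamDist:
    """Sampling recipe for one uncertain parameter: gamma for costs, beta
    for probabilities and utilities; sd = 0 collapses to the base value."""

    param: str
    kind: str          # "gamma" or "beta"
    mean: float
    sd: float

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.sd == 0.0 or self.mean == 0.0:
            return np.full(size, self.mean)
        if self.kind == "gamma":
            shape, scale = moments_to_gamma(self.mean, self.sd)
            return rng.gamma(shape, scale, size=size)
        if self.kind == "beta":
            alpha, beta = moments_to_beta(self.mean, self.sd)
            return rng.beta(alpha, beta, size=size)
        raise ValueError(f"unknown distribution kind {self.kind!r}")


def psa_parameter_distributions(config: CountryConfig,
                                rel: float = DEFAULT_RELATIVE_RANGE,
                                sd_scale: float = 1.0) -> list[ParamDist]:
    """Distribution assignments for every uncertain economic parameter.

    The spread treats the ±``rel`` DSA range as a 95% interval:
    sd = (high − low) / (2 × 1.96), optionally rescaled by ``sd_scale``
    (0 gives the degenerate point-mass PSA).
    """
    dists = []
    for param, base, bounded in _iter_parameter_ids(config):
        kind = "beta" if bounded else "gamma"
        sd = (2.0 * rel * base) / (2.0 * 1.96) * sd_scale
        if bounded and base > 0:
            # keep the beta variance feasible for means near 1
            sd = min(sd, 0.95 * math.sqrt(base * (1.0 - base))) \
                if base < 1.0 else 0.0
        dists.append(ParamDist(param, kind, base, sd))
    return dists


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSADraw:
    """Incremental outcomes of one Monte-Carlo draw."""

    draw: int
    delta_cost: float
    delta_qaly: float


def _perturbed_fits(fits: Mapping[str, ParametricFit],
                    rng: np.random.Generator) -> dict[str, ParametricFit]:
    out = {}
    for endpoint, fit in fits.items():
        params = tuple(fit.sample_params(rng, size=1)[0])
        out[endpoint] = ParametricFit(family=fit.family, params=params,
                                      loglik=fit.loglik, n_obs=fit.n_obs)
    return out


def run_psa(ctx: CEAContext, dists: Sequence[ParamDist] | None = None,
            n_draws: int = 5000, seed: int = 0,
            vary_survival: bool = True) -> list[PSADraw]:
    """Joint Monte-Carlo resampling of all uncertain inputs.

    Per draw, every economic parameter is sampled from its assigned
    distribution and (unless ``vary_survival`` is False) the four survival
    fits' parameters from their asymptotic normals; the model is rerun and
    (ΔC, ΔE) recorded.  Fixed seed ⇒ bit-identical draw sequence.
    """
    if dists is None:
        dists = psa_parameter_distributions(ctx.config)
    if n_draws <= 0:
        raise ValueError("n_draws must be > 0")
    # fail fast on infeasible assignments before any model run
    rng_check = np.random.default_rng(0)
    for d in dists:
        d.sample(rng_check, 1)

    rng = np.random.default_rng(seed)
    samples = {d.param: d.sample(rng, n_draws) for d in dists}

    draws: list[PSADraw] = []
    for i in range(n_draws):
        overrides = {param: float(vals[i]) for param, vals in samples.items()}
        if vary_survival:
            exp_fits = _perturbed_fits(ctx.exp_fits, rng)
            ctl_fits = _perturbed_fits(ctx.ctl_fits, rng)
        else:
            exp_fits = ctl_fits = None
        res = ctx.run(overrides=overrides, exp_fits=exp_fits,
                      ctl_fits=ctl_fits)
        draws.append(PSADraw(i, res.delta_cost, res.delta_qaly))
    return draws


def draws_to_frame(draws: Sequence[PSADraw]) -> pd.DataFrame:
    return pd.DataFrame({"draw": [d.draw for d in draws],
                         "delta_cost": [d.delta_cost for d in draws],
                         "delta_qaly": [d.delta_qaly for d in draws]})


# ---------------------------------------------------------------------------
# CEAC and ICE summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    probability: float


def default_wtp_grid() -> np.ndarray:
    """0 to 1.2 million USD/QALY in 201 points (covers every country's
    acceptability turning point)."""
    return np.linspace(0.0, 1.2e6, 201)


def ceac(draws: Sequence[PSADraw],
         wtp_grid: Sequence[float] | None = None) -> list[CEACPoint]:
    """Probability of positive net monetary benefit, λ·ΔE − ΔC > 0, per λ."""
    if not draws:
        raise ValueError("no PSA draws")
    grid = np.asarray(default_wtp_grid() if wtp_grid is None else wtp_grid,
                      dtype=float)
    dc = np.array([d.delta_cost for d in draws])
    de = np.array([d.delta_qaly for d in draws])
    nmb = grid[:, None] * de[None, :] - dc[None, :]
    prob = (nmb > 0).mean(axis=1)
    return [CEACPoint(float(w), float(p)) for w, p in zip(grid, prob)]


def ceac_to_frame(points: Sequence[CEACPoint]) -> pd.DataFrame:
    return pd.DataFrame({"wtp": [p.wtp for p in points],
                         "probability": [p.probability for p in points]})


def ice_quadrants(draws: Sequence[PSADraw]) -> dict[str, int]:
    """Quadrant counts of the ICE scatterplot.

    I: ΔE>0, ΔC>0; II: ΔE<0, ΔC>0; III: ΔE<0, ΔC<0; IV: ΔE>0, ΔC<0.
    Boundary points (a delta of exactly 0) count to the positive side.
    """
    if not draws:
        raise ValueError("no PSA draws")
    counts = {"I": 0, "II": 0, "III": 0, "IV": 0}
    for d in draws:
        e_pos = d.delta_qaly >= 0.0
        c_pos = d.delta_cost >= 0.0
        if e_pos and c_pos:
            counts["I"] += 1
        elif not e_pos and c_pos:
            counts["II"] += 1
        elif not e_pos and not c_pos:
            counts["III"] += 1
        else:
            counts["IV"] += 1
    return counts


# ---------------------------------------------------------------------------
# pembrolizumab price scenarios
# ---------------------------------------------------------------------------

def _icer_at_reduction(ctx: CEAContext, reduction: float) -> float:
    """ICER with the pembrolizumab vial price scaled by (1 − reduction);
    the scaling reaches both first-line use and the post-progression
    immunotherapy, which are priced off the same vial."""
    base_price = ctx.config.price("pembrolizumab").usd_per_vial
    res = ctx.run(overrides={
        "drug_price.pembrolizumab": base_price * (1.0 - reduction)
    })
    if res.status == "icer":
        return float(res.icer)
    if res.status == "dominant":
        return -math.inf
    raise RuntimeError(f"ICER undefined at reduction {reduction:.0%} "
                       f"(status {res.status})")


def scenario_price_grid(ctx: CEAContext,
                        reductions: Sequence[float] = DEFAULT_PRICE_REDUCTIONS
                        ) -> pd.DataFrame:
    """ICER at each pembrolizumab price reduction (fractions in [0, 1])."""
    rows = [{"reduction": float(r), "icer": _icer_at_reduction(ctx, float(r))}
            for r in reductions]
    return pd.DataFrame(rows)


def price_threshold_for_wtp(ctx: CEAContext, wtp: float,
                            tol: float = 0.001) -> float | None:
    """Smallest pembrolizumab price reduction bringing the ICER to ≤ wtp.

    Returns 0.0 when the base case is already cost-effective and None when
    even a free drug (100% reduction) is not ("not attainable").  The ICER
    is monotone decreasing in the reduction, so bisection to ``tol``
    brackets the answer.
    """
    if _icer_at_reduction(ctx, 0.0) <= wtp:
        return 0.0
    if _icer_at_reduction(ctx, 1.0) > wtp:
        return None
    lo, hi = 0.0, 1.0        # ICER(lo) > wtp >= ICER(hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _icer_at_reduction(ctx, mid) <= wtp:
            hi = mid
        else:
            lo = mid
    return hi
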