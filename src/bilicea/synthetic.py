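"""Synthetic two-arm trial generator.

Emulates the inputs the pipeline would normally take from a published
figure: per-subject PFS and OS times for a pembrolizumab + chemotherapy arm
(n = 533, median OS 12.7 months, median PFS 6.5 months) and a chemotherapy
arm (n = 536), with PFS ≤ OS enforced by construction (OS = PFS plus an
independent post-progression survival draw), administrative censoring and
uniform dropout, plus the digitized-curve and risk-table exports downstream
stages consume.

The control-arm medians are NOT published for this trial; the shipped
defaults (OS 10.9 months, PFS 5.6 months) are package choices made only so
that the experimental arm dominates on survival, and are plain
configuration parameters.

All sampling is inverse-CDF on a fixed uniform stream, so for a fixed seed
raising a median can only lengthen every subject's time (monotone
reparameterisation), and runs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate, optimize

from .fitting import FAMILIES, frozen_distribution
from .reconstruction import DigitizedKM, PseudoIPD, RiskTable, kaplan_meier

__all__ = [
    "ArmSpec",
    "default_experimental_arm",
    "default_control_arm",
    "sample_times",
    "generate_arm",
    "generate_trial",
    "export_digitized",
]

LN2 = math.log(2.0)


def sample_times(family: str, params: Sequence[float], n: int,
                 seed: int) -> np.ndarray:
    """Draw ``n`` i.i.d. event times from a parametric survival family.

    Sampling is by inverse CDF on uniforms from ``default_rng(seed)``, so a
    fixed seed yields an identical sequence.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    dist = frozen_distribution(family, params)
    rng = np.random.default_rng(seed)
    u = rng.uniform(1e-12, 1.0, size=n)
    return np.asarray(dist.ppf(u), dtype=float)


# ---------------------------------------------------------------------------
# arm specification and generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArmSpec:
    """Generation recipe for one trial arm (all times in months)."""

    n: int
    median_pfs: float
    median_os: float
    family: str = "exponential"
    weibull_shape: float = 1.5          # used only when family == "weibull"
    censor_time: float = 30.0           # administrative censoring horizon
    dropout_rate: float = 0.05          # fraction censored uniformly before it
    arm: str = "experimental"
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be > 0")
        if not 0 < self.median_pfs <= self.median_os:
            raise ValueError("need 0 < median_pfs <= median_os")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.family not in ("exponential", "weibull"):
            raise ValueError("generation family must be exponential or weibull")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be > 0")


def default_experimental_arm(seed: int = 42) -> ArmSpec:
    """The pembrolizumab + gemcitabine/cisplatin arm: n = 533, median OS
    12.7 months, median PFS 6.5 months."""
    return ArmSpec(n=533, median_pfs=6.5, median_os=12.7,
                   arm="experimental", seed=seed)


def default_control_arm(seed: int = 43) -> ArmSpec:
    """The gemcitabine/cisplatin arm: n = 536; medians are package defaults
    (no published control-arm medians exist for calibration)."""
    return ArmSpec(n=536, median_pfs=5.6, median_os=10.9,
                   arm="control", seed=seed)


def _pfs_family_params(spec: ArmSpec) -> tuple[str, tuple[float, ...]]:
    """PFS generation distribution, calibrated so its median is median_pfs."""
    if spec.family == "exponential":
        return "exponential", (LN2 / spec.median_pfs,)
    # weibull: scale fixed by median for the given shape
    scale = spec.median_pfs / LN2 ** (1.0 / spec.weibull_shape)
    return "weibull", (spec.weibull_shape, scale)


def _os_survival(t: float, pfs_dist, pps_rate: float) -> float:
    """Survival of OS = PFS + Exp(pps_rate) at time t (convolution)."""
    tail = float(pfs_dist.sf(t))
    if t <= 0:
        return 1.0
    integrand = lambda s: pfs_dist.pdf(s) * math.exp(-pps_rate * (t - s))
    val, _ = integrate.quad(integrand, 0.0, t, limit=200)
    return tail + val


def _calibrate_pps_rate(spec: ArmSpec) -> float:
    """Rate of the exponential post-progression survival such that the
    median of OS = PFS + PPS equals spec.median_os."""
    family, params = _pfs_family_params(spec)
    dist = frozen_distribution(family, params)
    if spec.median_os <= spec.median_pfs * (1.0 + 1e-9):
        raise ValueError(
            "median_os must exceed median_pfs to calibrate post-progression "
            "survival"
        )
    f = lambda rate: _os_survival(spec.median_os, dist, rate) - 0.5
    # f is increasing in rate? larger rate -> shorter PPS -> lower survival;
    # so f is decreasing in rate.  Bracket between a tiny and a huge rate.
    lo, hi = 1e-6, 1e4
    return float(optimize.brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))


def generate_arm(spec: ArmSpec) -> tuple[PseudoIPD, PseudoIPD]:
    """Generate per-subject (PFS, OS) pseudo-IPD for one arm.

    Per subject, OS = PFS + an exponential post-progression draw whose rate
    is calibrated so the OS distribution's median equals ``spec.median_os``;
    both endpoints share one censoring time per subject (administrative at
    ``censor_time``, or earlier uniform dropout with probability
    ``dropout_rate``).  Returns ``(pfs_ipd, os_ipd)``.
    """
    family, params = _pfs_family_params(spec)
    pfs_dist = frozen_distribution(family, params)
    pps_rate = _calibrate_pps_rate(spec)

    rng = np.random.default_rng(spec.seed)
    u_pfs = rng.uniform(1e-12, 1.0, size=spec.n)
    u_pps = rng.uniform(1e-12, 1.0, size=spec.n)
    u_drop = rng.uniform(0.0, 1.0, size=spec.n)
    u_drop_t = rng.uniform(1e-9, 1.0, size=spec.n)

    t_pfs = np.asarray(pfs_dist.ppf(u_pfs), dtype=float)
    t_pps = -np.log(u_pps) / pps_rate
    t_os = t_pfs + t_pps

    censor = np.where(u_drop < spec.dropout_rate,
                      u_drop_t * spec.censor_time, spec.censor_time)

    pfs_obs = np.minimum(t_pfs, censor)
    pfs_event = (t_pfs <= censor).astype(int)
    os_obs = np.minimum(t_os, censor)
    os_event = (t_os <= censor).astype(int)

    pfs_ipd = PseudoIPD(pfs_obs, pfs_event, endpoint="PFS", arm=spec.arm)
    os_ipd = PseudoIPD(os_obs, os_event, endpoint="OS", arm=spec.arm)
    return pfs_ipd, os_ipd


def generate_trial(seed: int = 42) -> dict[str, dict[str, PseudoIPD]]:
    """Both default arms as ``{arm: {"PFS": ipd, "OS": ipd}}``.

    Arm-level seeds are derived deterministically from ``seed`` so the two
    arms use independent streams.
    """
    exp_spec = default_experimental_arm(seed=seed)
    ctl_spec = default_control_arm(seed=seed + 104729)   # offset by a prime
    out = {}
    for spec in (exp_spec, ctl_spec):
        pfs, os_ = generate_arm(spec)
        out[spec.arm] = {"PFS": pfs, "OS": os_}
    return out


# ---------------------------------------------------------------------------
# digitized exports
# ---------------------------------------------------------------------------

def export_digitized(ipd: PseudoIPD, grid: Sequence[float],
                     risk_interval: float) -> tuple[DigitizedKM, RiskTable]:
    """Evaluate the KM curve of ``ipd`` on a time grid and count numbers at
    risk at every multiple of ``risk_interval`` — the shape of a published
    figure plus its risk table."""
    if ipd.n == 0:
        raise ValueError("cannot export an empty cohort")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0) or grid[0] < 0:
        raise ValueError("grid must be non-empty, strictly increasing, >= 0")
    if risk_interval <= 0:
        raise ValueError("risk_interval must be > 0")

    km = kaplan_meier(ipd)
    surv = np.asarray(km(grid), dtype=float)
    curve = DigitizedKM(grid, surv, endpoint=ipd.endpoint, arm=ipd.arm)

    t_max = float(ipd.times.max())
    n_points = int(math.floor(t_max / risk_interval)) + 1
    risk_times = np.arange(n_points) * risk_interval
    n_at_risk = (ipd.times[None, :] >= risk_times[:, None]).sum(axis=1)
    # by convention everyone is at risk at t = 0
    n_at_risk[0] = ipd.n
    table = RiskTable(risk_times, n_at_risk)
    return curve, table
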