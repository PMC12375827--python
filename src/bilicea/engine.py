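"""Three-state partitioned survival model and ICER computation.

State occupancy is read directly off the fitted OS and PFS curves at each
cycle's evaluation time t_i:

    π_pfs(i)   = min(S_pfs(t_i), S_os(t_i))
    π_death(i) = 1 − S_os(t_i)
    π_pd(i)    = S_os(t_i) − π_pfs(i)

so the three occupancies always sum to one and no transition probabilities
are needed.  Costs and QALYs accrue per 21-day cycle: first-line drugs and
administration to PFS occupants (pembrolizumab capped at 35 cycles,
cisplatin at 8), examination to everyone alive, a proportion-weighted mix
of FOLFOX / immunotherapy / best supportive care to progressed occupants,
adverse-event management once in the first cycle, and a one-time
end-of-life cost on each cycle's incremental deaths.  Everything is
discounted at (1 + r)^(−t in years) and summed to discounted totals, an
incremental cost, an incremental QALY and an ICER (or a dominance status
when the signs make a ratio meaningless).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .config import (
    AE_NAMES,
    CountryConfig,
    FOLFOX_CYCLE_FACTOR,
    ModelSettings,
    RegimenComponent,
    first_line_regimen,
    folfox_course,
    io_regimen,
)
from .fitting import ParametricFit, survival_at

__all__ = [
    "COST_CATEGORIES",
    "StateTrajectory",
    "ArmResult",
    "CEAResult",
    "build_trajectory",
    "drug_cost_cycle",
    "second_line_cost_cycle",
    "ae_cost_first_cycle",
    "discount_factor",
    "accrue",
    "run_cea",
]

COST_CATEGORIES = (
    "drug_first_line",
    "drug_second_line",
    "administration",
    "examination",
    "adverse_events",
    "best_supportive_care",
    "end_of_life",
)

# second-line categories folded into drug_second_line vs BSC
_SIGN_TOL = 1e-12


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------

@dataclass
class StateTrajectory:
    """Per-cycle state occupancy (cycles indexed 0..n_cycles−1)."""

    eval_times: np.ndarray     # months at which occupancy is evaluated
    pi_pfs: np.ndarray
    pi_pd: np.ndarray
    pi_death: np.ndarray

    @property
    def n_cycles(self) -> int:
        return int(self.eval_times.size)

    def validate(self, atol: float = 1e-12) -> None:
        total = self.pi_pfs + self.pi_pd + self.pi_death
        if not np.allclose(total, 1.0, atol=atol, rtol=0.0):
            raise ValueError("state occupancies do not sum to 1")
        if np.any(np.diff(self.pi_death) < -atol):
            raise ValueError("death occupancy decreases")
        if np.any(np.diff(self.pi_pfs) > atol):
            raise ValueError("PFS occupancy increases")


def build_trajectory(os_fit: ParametricFit, pfs_fit: ParametricFit,
                     settings: ModelSettings) -> StateTrajectory:
    """Partitioned-survival occupancy over the model horizon.

    Occupancy is evaluated at each cycle start (t_i = i × cycle length), or
    at cycle midpoints when ``settings.half_cycle_correction`` is set.
    """
    i = np.arange(settings.n_cycles, dtype=float)
    if settings.half_cycle_correction:
        i = i + 0.5
    t = i * settings.cycle_months
    s_os = np.asarray(survival_at(os_fit, t), dtype=float)
    s_pfs = np.asarray(survival_at(pfs_fit, t), dtype=float)
    pi_pfs = np.minimum(s_pfs, s_os)
    pi_death = 1.0 - s_os
    pi_pd = s_os - pi_pfs
    return StateTrajectory(eval_times=t, pi_pfs=pi_pfs, pi_pd=pi_pd,
                           pi_death=pi_death)


# ---------------------------------------------------------------------------
# per-cycle cost primitives
# ---------------------------------------------------------------------------

def _administration_cost(component: RegimenComponent, config: CountryConfig
                         ) -> float:
    """Cost of the vials for one cycle of one regimen component."""
    price = config.price(component.drug_name)
    dose = component.dose_mg * (config.bsa if component.per_m2 else 1.0)
    vials = math.ceil(dose / price.vial_mg - 1e-9)
    return vials * price.usd_per_vial * component.administrations_per_cycle


def drug_cost_cycle(arm: str, cycle_index: int, config: CountryConfig) -> float:
    """Undiscounted first-line drug cost of treatment cycle ``cycle_index``
    (1-based) for a patient who spends the whole cycle progression-free.

    Doses in mg/m² are scaled by the country's mean body surface area and
    rounded up to whole vials (no vial sharing); a component contributes
    nothing once ``cycle_index`` exceeds its maximum number of cycles.
    """
    if cycle_index < 1:
        raise ValueError("cycle_index is 1-based")
    total = 0.0
    for component in first_line_regimen(arm):
        if component.max_cycles is not None and cycle_index > component.max_cycles:
            continue
        total += _administration_cost(component, config)
    return total


def _drug_cost_schedule(arm: str, config: CountryConfig,
                        n_cycles: int) -> np.ndarray:
    """Vectorized per-cycle first-line drug costs for cycles 1..n_cycles."""
    cycles = np.arange(1, n_cycles + 1)
    costs = np.zeros(n_cycles)
    for component in first_line_regimen(arm):
        per_cycle = _administration_cost(component, config)
        if component.max_cycles is None:
            costs += per_cycle
        else:
            costs[cycles <= component.max_cycles] += per_cycle
    return costs


def folfox_cycle_cost(config: CountryConfig) -> float:
    """FOLFOX cost per 21-day model cycle: one 14-day course prorated by
    21/14."""
    course = sum(_administration_cost(c, config) for c in folfox_course())
    return course * FOLFOX_CYCLE_FACTOR


def io_cycle_cost(config: CountryConfig) -> float:
    """Post-progression immunotherapy cost per cycle (one 200 mg
    pembrolizumab administration)."""
    return sum(_administration_cost(c, config) for c in io_regimen())


def second_line_cost_cycle(arm: str, config: CountryConfig) -> float:
    """Expected post-progression cost per cycle per unit of PD occupancy:
    a proportion-weighted mix of FOLFOX, immunotherapy and best supportive
    care, with arm-specific proportions."""
    if arm == "experimental":
        p_folfox = config.second_line_prop_pem
        p_io = config.io_prop_pem
    elif arm == "control":
        p_folfox = config.second_line_prop_chem
        p_io = config.io_prop_chem
    else:
        raise ValueError(f"unknown arm {arm!r}")
    p_bsc = 1.0 - p_folfox - p_io
    return (p_folfox * folfox_cycle_cost(config)
            + p_io * io_cycle_cost(config)
            + p_bsc * config.bsc_cost)


def ae_cost_first_cycle(arm: str, config: CountryConfig) -> float:
    """Expected grade ≥3 adverse-event management cost, applied once to the
    whole cohort in the first treatment cycle."""
    probs = config.ae_prob_pem if arm == "experimental" else config.ae_prob_chem
    if arm not in ("experimental", "control"):
        raise ValueError(f"unknown arm {arm!r}")
    total = 0.0
    for ae in AE_NAMES:
        try:
            total += probs[ae] * config.ae_costs[ae]
        except KeyError:
            raise ValueError(f"missing adverse-event entry {ae!r}") from None
    return total


def discount_factor(cycle_index: int | np.ndarray, rate: float,
                    cycle_days: float = 21.0) -> float | np.ndarray:
    """(1 + rate)^(−cycle_index × cycle_days / 365.25); 1 at cycle 0."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    years = np.asarray(cycle_index, dtype=float) * cycle_days / 365.25
    out = (1.0 + rate) ** (-years)
    return out if np.ndim(cycle_index) else float(out)


# ---------------------------------------------------------------------------
# accrual
# ---------------------------------------------------------------------------

@dataclass
class ArmResult:
    """Discounted totals for one arm, with a cost breakdown by category."""

    total_cost: float
    total_qaly: float
    breakdown: dict[str, float] = field(default_factory=dict)

    def validate(self, atol: float = 1e-6) -> None:
        if abs(sum(self.breakdown.values()) - self.total_cost) > atol:
            raise ValueError("cost breakdown does not sum to total")
        if any(v < -atol for v in self.breakdown.values()):
            raise ValueError("negative cost component")


def accrue(traj: StateTrajectory, arm: str, config: CountryConfig,
           settings: ModelSettings) -> ArmResult:
    """Accumulate discounted costs and QALYs over the trajectory.

    Cycle j (0-based row, treatment cycle j+1) contributes

    * π_pfs(j) × (first-line drug cost of cycle j+1 + administration cost)
    * (π_pfs(j) + π_pd(j)) × examination cost
    * π_pd(j) × expected second-line cost
    * (π_death(j) − π_death(j−1)) × end-of-life cost
    * the expected AE cost once, at treatment cycle 1,

    each multiplied by the cycle's discount factor, and

    * QALYs (cycle length in years) × (u_pfs π_pfs + u_pd π_pd), discounted.
    """
    n = traj.n_cycles
    j = np.arange(n)
    df = np.asarray(discount_factor(j, config.discount_rate,
                                    settings.cycle_days))
    pfs, pd_, death = traj.pi_pfs, traj.pi_pd, traj.pi_death
    alive = pfs + pd_
    new_deaths = np.diff(death, prepend=death[0])
    new_deaths[0] = death[0]          # deaths before the first evaluation

    drug = _drug_cost_schedule(arm, config, n)
    sl = second_line_cost_cycle(arm, config)
    ae = ae_cost_first_cycle(arm, config)

    components = {
        "drug_first_line": float(np.sum(pfs * drug * df)),
        "administration": float(np.sum(pfs * config.administration_cost * df)),
        "examination": float(np.sum(alive * config.examination_cost * df)),
        "drug_second_line": float(np.sum(pd_ * sl * df)),
        "adverse_events": float(ae * df[0]),
        "end_of_life": float(np.sum(new_deaths * config.eol_cost * df)),
    }
    # the BSC share is already inside the second-line mix; report it within
    # that category rather than double-counting
    components["best_supportive_care"] = 0.0

    qaly = float(np.sum(
        settings.cycle_years * (config.u_pfs * pfs + config.u_pd * pd_) * df
    ))
    total = float(sum(components.values()))
    return ArmResult(total_cost=total, total_qaly=qaly, breakdown=components)


# ---------------------------------------------------------------------------
# incremental analysis
# ---------------------------------------------------------------------------

@dataclass
class CEAResult:
    """Incremental comparison of the experimental vs control strategies."""

    experimental: ArmResult
    control: ArmResult
    country: str = ""

    @property
    def delta_cost(self) -> float:
        return self.experimental.total_cost - self.control.total_cost

    @property
    def delta_qaly(self) -> float:
        return self.experimental.total_qaly - self.control.total_qaly

    @property
    def status(self) -> str:
        """'icer', 'dominant', 'dominated' or 'undefined'."""
        dq, dc = self.delta_qaly, self.delta_cost
        if abs(dq) < _SIGN_TOL:
            return "undefined" if abs(dc) >= _SIGN_TOL else "icer"
        if dq > 0 and dc < 0:
            return "dominant"
        if dq < 0 and dc > 0:
            return "dominated"
        return "icer"

    @property
    def icer(self) -> float | None:
        """USD per QALY, or None when a dominance status applies."""
        if self.status != "icer":
            return None
        if abs(self.delta_qaly) < _SIGN_TOL:
            return 0.0                # both deltas negligible
        return self.delta_cost / self.delta_qaly

    def icer_or_status(self) -> float | str:
        return self.icer if self.status == "icer" else self.status

    def to_frame_rows(self) -> list[dict]:
        """Table-2-shaped rows (one per arm) for :func:`config.write_results`."""
        icer = self.icer_or_status()
        return [
            {
                "country": self.country,
                "arm": "experimental",
                "cost": self.experimental.total_cost,
                "qaly": self.experimental.total_qaly,
                "incremental_cost": self.delta_cost,
                "incremental_qaly": self.delta_qaly,
                "icer": icer,
            },
            {
                "country": self.country,
                "arm": "control",
                "cost": self.control.total_cost,
                "qaly": self.control.total_qaly,
                "incremental_cost": None,
                "incremental_qaly": None,
                "icer": None,
            },
        ]

    def to_dict(self) -> dict:
        return {
            "country": self.country,
            "experimental": {"cost": self.experimental.total_cost,
                             "qaly": self.experimental.total_qaly,
                             "breakdown": self.experimental.breakdown},
            "control": {"cost": self.control.total_cost,
                        "qaly": self.control.total_qaly,
                        "breakdown": self.control.breakdown},
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "status": self.status,
            "icer": self.icer,
        }


def run_cea(exp_fits: Mapping[str, ParametricFit],
            ctl_fits: Mapping[str, ParametricFit],
            config: CountryConfig,
            settings: ModelSettings | None = None) -> CEAResult:
    """Run the full economic comparison.

    ``exp_fits`` and ``ctl_fits`` each map endpoint ("OS"/"PFS") to the
    selected parametric fit for that arm.
    """
    settings = settings or ModelSettings()
    results = {}
    for arm, fits in (("experimental", exp_fits), ("control", ctl_fits)):
        missing = {"OS", "PFS"} - set(fits)
        if missing:
            raise ValueError(f"{arm} arm is missing fit(s) for {sorted(missing)}")
        traj = build_trajectory(fits["OS"], fits["PFS"], settings)
        results[arm] = accrue(traj, arm, config, settings)
    return CEAResult(experimental=results["experimental"],
                     control=results["control"], country=config.country)
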