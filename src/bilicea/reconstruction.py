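"""Kaplan–Meier estimation and pseudo-IPD reconstruction from digitized curves.

Published trial figures give a survival curve and a numbers-at-risk table
but no per-subject data.  This module inverts that: from digitized step
coordinates plus the risk table it rebuilds per-subject (time, event)
records using the interval-by-interval allocation scheme of Guyot et al.
(censoring assumed uniform within each risk-table interval, event counts
solved so the reconstructed product-limit curve tracks the digitized drops,
with an optional global event-total constraint).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = [
    "PseudoIPD",
    "DigitizedKM",
    "RiskTable",
    "KMCurve",
    "kaplan_meier",
    "reconstruct_ipd",
    "reconstruction_error",
    "ReconstructionError",
]

#: digitization noise beyond which a survival increase is treated as a real
#: inconsistency rather than hand-digitization jitter
MONOTONICITY_TOLERANCE = 0.005


class ReconstructionError(ValueError):
    """Raised for inconsistent or infeasible digitized inputs."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PseudoIPD:
    """Per-subject (time, event) records for one endpoint of one arm.

    ``events`` is 1 for an observed event and 0 for right censoring; all
    times are months and strictly positive.
    """

    times: np.ndarray
    events: np.ndarray
    endpoint: str = "OS"
    arm: str = "experimental"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must have equal length")
        if self.times.size and not np.all(self.times > 0):
            raise ValueError("all times must be > 0")
        if self.times.size and not np.isin(self.events, (0, 1)).all():
            raise ValueError("events must be 0 or 1")

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "event": self.events})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, endpoint: str = "OS",
                 arm: str = "experimental") -> "PseudoIPD":
        frame = pd.read_csv(path)
        return cls(frame["time_months"].to_numpy(),
                   frame["event"].to_numpy(), endpoint=endpoint, arm=arm)


@dataclass
class DigitizedKM:
    """Step coordinates of a published survival curve (time in months)."""

    times: np.ndarray
    survival: np.ndarray
    endpoint: str = "OS"
    arm: str = "experimental"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times.size == 0:
            raise ReconstructionError("digitized curve is empty")
        if self.times.shape != self.survival.shape:
            raise ReconstructionError("times and survival must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ReconstructionError("digitized times must be strictly increasing")
        if self.times[0] < 0:
            raise ReconstructionError("digitized times must be >= 0")

    def cleaned(self) -> "DigitizedKM":
        """Clip survival to [0, 1] and enforce monotone non-increase.

        Violations within ``MONOTONICITY_TOLERANCE`` are treated as
        digitization noise and flattened by a running-minimum pass; larger
        increases are an input error.
        """
        s = np.clip(self.survival, 0.0, 1.0)
        rises = np.diff(s)
        if rises.size and rises.max() > MONOTONICITY_TOLERANCE:
            i = int(np.argmax(rises > MONOTONICITY_TOLERANCE))
            raise ReconstructionError(
                f"survival increases by {rises[i + 0]:.4f} at "
                f"t={self.times[i + 1]:.3f}; exceeds digitization tolerance"
            )
        s = np.minimum.accumulate(s)
        return DigitizedKM(self.times.copy(), s, self.endpoint, self.arm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "survival": self.survival})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, endpoint: str = "OS",
                 arm: str = "experimental") -> "DigitizedKM":
        frame = pd.read_csv(path)
        return cls(frame["time_months"].to_numpy(),
                   frame["survival"].to_numpy(), endpoint=endpoint, arm=arm)


@dataclass
class RiskTable:
    """Numbers at risk at (strictly increasing) times, starting at t = 0."""

    times: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.n_at_risk = np.asarray(self.n_at_risk, dtype=int)
        if self.times.size == 0:
            raise ReconstructionError("risk table is empty")
        if self.times.shape != self.n_at_risk.shape:
            raise ReconstructionError("risk table columns must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ReconstructionError("risk-table times must be strictly increasing")
        if self.times[0] != 0:
            raise ReconstructionError("risk table must start at time 0")
        if np.any(np.diff(self.n_at_risk) > 0):
            raise ReconstructionError("risk counts increase over time")
        if np.any(self.n_at_risk < 0):
            raise ReconstructionError("negative risk counts")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "n_at_risk": self.n_at_risk})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RiskTable":
        frame = pd.read_csv(path)
        return cls(frame["time_months"].to_numpy(), frame["n_at_risk"].to_numpy())


# ---------------------------------------------------------------------------
# Kaplan–Meier estimation
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """A right-continuous product-limit step function, S(0) = 1."""

    times: np.ndarray        # event/censor grid of the fitted estimate
    survival: np.ndarray     # S evaluated at those times (right-continuous)
    median: float            # months; inf when S never reaches 0.5

    def __call__(self, t) -> np.ndarray | float:
        """Evaluate S(t) (right-continuous: the drop at t is included)."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t_arr, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return out if np.ndim(t) else float(out[0])


def kaplan_meier(ipd: PseudoIPD) -> KMCurve:
    """Product-limit estimate of the survival function of ``ipd``."""
    if ipd.n == 0:
        raise ValueError("cannot estimate a survival curve from zero subjects")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, event_observed=ipd.events)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    if times[0] != 0.0:                      # anchor S(0) = 1 explicitly
        times = np.concatenate([[0.0], times])
        surv = np.concatenate([[1.0], surv])
    median = float(kmf.median_survival_time_)
    return KMCurve(times=times, survival=surv, median=median)


def number_at_risk(ipd: PseudoIPD, times: Sequence[float]) -> np.ndarray:
    """Subjects still under observation at each time (observed time >= t)."""
    t = np.asarray(times, dtype=float)
    return (ipd.times[None, :] >= t[:, None]).sum(axis=1)


# ---------------------------------------------------------------------------
# Guyot-style reconstruction
# ---------------------------------------------------------------------------

def reconstruct_ipd(curve: DigitizedKM, risk: RiskTable | None = None,
                    total_events: int | None = None,
                    n0: int | None = None) -> PseudoIPD:
    """Rebuild pseudo-IPD from a digitized curve and its risk table.

    Within each risk-table interval, censorings are spread uniformly and
    their count iterated until the implied number at risk at the next table
    time matches the published one; event counts at each digitized step are
    solved from the product-limit drop ratios.  With no risk table, no
    censoring is assumed before the last plotted time (a loud warning is
    emitted) and ``n0`` must supply the arm size.  If ``total_events`` is
    given, the output's event count is forced to it exactly by flipping the
    latest censored records to events (or vice versa).
    """
    curve = curve.cleaned()
    t = curve.times
    s = curve.survival
    if t[0] > 0.0:                            # anchor the curve at (0, 1)
        t = np.concatenate([[0.0], t])
        s = np.concatenate([[1.0], s])

    if risk is None:
        if n0 is None:
            raise ReconstructionError("without a risk table, n0 is required")
        warnings.warn(
            "no risk table supplied: assuming no censoring before the last "
            "digitized time; reconstructed censoring pattern is unreliable",
            stacklevel=2,
        )
        risk = RiskTable(np.array([0.0]), np.array([n0]))
    if risk.times[-1] > t[-1]:
        raise ReconstructionError("risk table extends beyond the digitized curve")

    K = t.size
    # boundaries of risk intervals in point-index space
    tau = risk.times
    n_pub = risk.n_at_risk
    J = tau.size
    lower = np.searchsorted(t, tau, side="left")

    d = np.zeros(K, dtype=int)                # events at each digitized point
    c = np.zeros(K, dtype=int)                # censored within [t[i], t[i+1])
    cen_times: list[list[float]] = [[] for _ in range(K)]
    n_at = np.zeros(K + 1, dtype=int)
    n_at[lower[0]] = n_pub[0]

    s_last_event = 1.0                        # running KM value at last event
    for j in range(J):
        i_lo = lower[j]
        i_hi = lower[j + 1] if j + 1 < J else K
        if i_lo >= i_hi:
            raise ReconstructionError(
                f"risk interval starting at t={tau[j]:.3f} contains no "
                "digitized points"
            )
        has_next = j + 1 < J
        if has_next and s[i_lo] <= 0:
            c_guess = 0
        elif has_next:
            c_guess = int(round(n_at[i_lo] * s[i_hi] / s[i_lo])) - int(n_pub[j + 1])
        else:
            c_guess = 0                       # last interval: no censoring assumed
        c_guess = max(c_guess, 0)

        t_end = tau[j + 1] if has_next else t[-1]
        best = None
        for _ in range(40):
            # spread c_guess censorings uniformly over (tau_j, t_end)
            if c_guess > 0:
                cen = tau[j] + (np.arange(1, c_guess + 1) / (c_guess + 1)) \
                    * (t_end - tau[j])
            else:
                cen = np.empty(0)
            c_trial = np.zeros(K, dtype=int)
            cen_trial: dict[int, list[float]] = {}
            for ct in cen:
                i = min(np.searchsorted(t, ct, side="right") - 1, K - 1)
                i = max(i, i_lo)
                c_trial[i] += 1
                cen_trial.setdefault(i, []).append(float(ct))
            # walk the digitized points, solving event counts from KM drops
            n_i = n_at[i_lo]
            d_trial = np.zeros(K, dtype=int)
            s_le = s_last_event
            for i in range(i_lo, i_hi):
                if s_le > 0 and n_i > 0:
                    d_i = int(round(n_i * (1.0 - s[i] / s_le)))
                else:
                    d_i = 0
                d_i = int(np.clip(d_i, 0, n_i))
                if d_i > 0:
                    s_le = s_le * (1.0 - d_i / n_i)
                d_trial[i] = d_i
                n_i = n_i - d_i - c_trial[i]
            n_end = n_i
            best = (d_trial, c_trial, cen_trial, s_le, n_end)
            if not has_next:
                break
            gap = n_end - int(n_pub[j + 1])
            if gap == 0:
                break
            new_guess = max(c_guess + gap, 0)
            if new_guess == c_guess:
                break
            c_guess = new_guess
        assert best is not None
        d_trial, c_trial, cen_trial, s_le, n_end = best
        d[i_lo:i_hi] = d_trial[i_lo:i_hi]
        c[i_lo:i_hi] = c_trial[i_lo:i_hi]
        for i, lst in cen_trial.items():
            cen_times[i] = lst
        s_last_event = s_le
        if has_next:
            n_at[i_hi] = n_end

    # remaining subjects after the last digitized point: censored at t[-1]
    leftover = int(n_pub[0] - d.sum() - c.sum())
    times_out: list[float] = []
    events_out: list[int] = []
    for i in range(K):
        if d[i] > 0:
            if t[i] <= 0:
                raise ReconstructionError("events allocated at time zero")
            times_out.extend([t[i]] * d[i])
            events_out.extend([1] * d[i])
        for ct in cen_times[i]:
            times_out.extend([max(ct, np.nextafter(0.0, 1.0))])
            events_out.append(0)
    if leftover > 0:
        times_out.extend([t[-1]] * leftover)
        events_out.extend([0] * leftover)

    times_arr = np.asarray(times_out, dtype=float)
    events_arr = np.asarray(events_out, dtype=int)
    order = np.argsort(times_arr, kind="stable")
    ipd = PseudoIPD(times_arr[order], events_arr[order],
                    endpoint=curve.endpoint, arm=curve.arm)

    if total_events is not None:
        ipd = _force_event_total(ipd, total_events)
    return ipd


def _force_event_total(ipd: PseudoIPD, total_events: int) -> PseudoIPD:
    """Flip the latest censored records to events (or vice versa) until the
    event count equals ``total_events``."""
    if not 0 <= total_events <= ipd.n:
        raise ReconstructionError(
            f"total_events={total_events} infeasible for n={ipd.n}"
        )
    events = ipd.events.copy()
    deficit = total_events - int(events.sum())
    if deficit > 0:
        idx = np.nonzero(events == 0)[0]
        if idx.size < deficit:
            raise ReconstructionError("not enough censored records to convert")
        events[idx[-deficit:]] = 1
    elif deficit < 0:
        idx = np.nonzero(events == 1)[0]
        events[idx[deficit:]] = 0
    return PseudoIPD(ipd.times.copy(), events, ipd.endpoint, ipd.arm)


def reconstruction_error(original: DigitizedKM, recon: PseudoIPD) -> float:
    """Max absolute deviation between the digitized curve and the KM curve of
    the reconstruction, over the digitized time points."""
    if original.times.size == 0 or recon.n == 0:
        raise ValueError("both inputs must be non-empty")
    km = kaplan_meier(recon)
    dev = np.abs(original.survival - km(original.times))
    return float(dev.max())
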