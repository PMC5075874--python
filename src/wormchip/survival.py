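"""Survival curves for on-chip and plate killing assays.

On a chip no worm is ever lost, so the survival curve is simply the fraction
of worms still alive at each frame, S(t) = alive(t) / n0, with binomial
standard errors (Greenwood's formula reduces to this with no censoring).
Plate assays lose 10-20% of worms, which must be censored; the product-limit
(Kaplan-Meier) estimator handles that:

    S(t) = prod_{t_i <= t} (1 - d_i / n_i)

over distinct death times t_i with d_i deaths among n_i at risk, censored
subjects leaving the risk set after their censor time.  With zero censoring
the two estimators coincide exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_STATUS = ("died", "censored", "alive_at_end")


@dataclass(frozen=True)
class SurvivalRecord:
    subject_id: str
    event_time_h: float
    status: str  # died | censored | alive_at_end

    def __post_init__(self) -> None:
        if self.event_time_h < 0:
            raise ValueError("event_time_h must be >= 0")
        if self.status not in VALID_STATUS:
            raise ValueError(f"status must be one of {VALID_STATUS}")


@dataclass
class SurvivalCurve:
    time_h: np.ndarray
    survival: np.ndarray
    std_err: np.ndarray
    n_at_risk: np.ndarray
    method: str  # empirical_chip | kaplan_meier
    corrected: bool = False  # isotonic correction was applied (chip mode)

    def at(self, t: float) -> float:
        """Step-function value of S at time t."""
        idx = np.searchsorted(self.time_h, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_h": self.time_h, "survival": self.survival,
             "std_err": self.std_err, "n_at_risk": self.n_at_risk}
        )


def _pava_decreasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators fit for a non-increasing sequence."""
    y = np.asarray(y, dtype=float)
    blocks = [[v, 1] for v in y]  # (mean, weight)
    merged = []
    for b in blocks:
        merged.append(b)
        while len(merged) > 1 and merged[-2][0] < merged[-1][0]:
            m2, w2 = merged.pop()
            m1, w1 = merged.pop()
            merged.append([(m1 * w1 + m2 * w2) / (w1 + w2), w1 + w2])
    out = []
    for m, w in merged:
        out.extend([m] * w)
    return np.array(out)


def chip_survival(
    alive_counts: Sequence[int],
    times_h: Sequence[float],
    initial_n: int,
) -> SurvivalCurve:
    """Empirical survival from per-frame alive counts (no censoring possible).

    Counts that transiently rise (segmentation jitter) are corrected with a
    pool-adjacent-violators isotonic fit before dividing by ``initial_n``.
    """
    counts = np.asarray(alive_counts, dtype=float)
    times = np.asarray(times_h, dtype=float)
    if initial_n < 1:
        raise ValueError("initial_n must be >= 1")
    if len(counts) != len(times):
        raise ValueError("alive_counts and times_h must have equal length")
    order = np.argsort(times, kind="stable")
    counts, times = counts[order], times[order]
    corrected = bool(np.any(np.diff(counts) > 0))
    if corrected:
        counts = _pava_decreasing(counts)
    S = np.clip(counts / initial_n, 0.0, 1.0)
    se = np.sqrt(S * (1 - S) / initial_n)
    return SurvivalCurve(times, S, se, counts.astype(int), "empirical_chip", corrected)


def kaplan_meier(records: Iterable[SurvivalRecord]) -> SurvivalCurve:
    """Product-limit estimator with Greenwood standard errors.

    Deaths at a given time are processed before censorings at the same time
    (the standard convention).  ``alive_at_end`` records are censored at
    their event time.
    """
    recs = list(records)
    if not recs:
        raise ValueError("need at least one record")
    events = sorted({r.event_time_h for r in recs if r.status == "died"})
    n = len(recs)
    if not events:
        import warnings

        warnings.warn("all records censored: survival curve is identically 1")
        tmax = max(r.event_time_h for r in recs)
        return SurvivalCurve(
            np.array([0.0, tmax]), np.ones(2), np.zeros(2),
            np.array([n, 0]), "kaplan_meier",
        )
    times = [0.0] + events
    S, se, at_risk = [1.0], [0.0], [n]
    s = 1.0
    greenwood = 0.0
    for t in events:
        # a subject censored exactly at t is still at risk for deaths at t
        n_i = sum(1 for r in recs if r.event_time_h >= t)
        d_i = sum(1 for r in recs if r.status == "died" and r.event_time_h == t)
        s *= 1.0 - d_i / n_i
        if n_i > d_i:
            greenwood += d_i / (n_i * (n_i - d_i))
        S.append(s)
        se.append(s * math.sqrt(greenwood))
        at_risk.append(n_i - d_i)
    return SurvivalCurve(
        np.array(times), np.array(S), np.array(se),
        np.array(at_risk), "kaplan_meier",
    )


def lost_fraction_course(
    records: Iterable[SurvivalRecord] | None = None,
    times_h: Sequence[float] | None = None,
    chip_mode: bool = False,
) -> pd.DataFrame:
    """Cumulative fraction of worms censored as lost, over time.

    Chip mode returns identically zero: worms cannot leave the chamber.
    """
    if chip_mode:
        t = np.asarray(times_h if times_h is not None else [0.0], dtype=float)
        return pd.DataFrame({"time_h": t, "lost_fraction": np.zeros(len(t))})
    recs = list(records or [])
    if not recs:
        raise ValueError("records required when not in chip mode")
    n = len(recs)
    censor_times = sorted(r.event_time_h for r in recs if r.status == "censored")
    if times_h is None:
        grid = sorted({0.0, *{r.event_time_h for r in recs}})
    else:
        grid = list(times_h)
    frac = [sum(1 for ct in censor_times if ct <= t) / n for t in grid]
    return pd.DataFrame({"time_h": grid, "lost_fraction": frac})


@dataclass
class CurveComparison:
    median_a: float  # math.inf encodes "> Tmax"
    median_b: float
    median_sentinel_a: str | None
    median_sentinel_b: str | None
    pointwise_diff: pd.DataFrame
    logrank_stat: float | None = None
    logrank_p: float | None = None


def median_survival(curve: SurvivalCurve) -> tuple[float, str | None]:
    """First time at which S <= 0.5 (linear interpolation between grid points).

    Returns ``(inf, "> Tmax")`` when the curve never reaches 0.5.
    """
    S, t = curve.survival, curve.time_h
    below = np.nonzero(S <= 0.5)[0]
    if len(below) == 0:
        return math.inf, f">{t[-1]:g}"
    i = below[0]
    if i == 0 or S[i] == 0.5 or S[i - 1] == S[i]:
        return float(t[i]), None
    frac = (S[i - 1] - 0.5) / (S[i - 1] - S[i])
    return float(t[i - 1] + frac * (t[i] - t[i - 1])), None


def compare_curves(
    curve_a: SurvivalCurve,
    curve_b: SurvivalCurve,
    records_a: Iterable[SurvivalRecord] | None = None,
    records_b: Iterable[SurvivalRecord] | None = None,
) -> CurveComparison:
    """Median survival times, pointwise differences and (optionally) log-rank.

    The log-rank test needs the underlying event records; it is computed with
    lifelines when both record sets are given.
    """
    med_a, sent_a = median_survival(curve_a)
    med_b, sent_b = median_survival(curve_b)
    grid = np.union1d(curve_a.time_h, curve_b.time_h)
    lo = max(curve_a.time_h.min(), curve_b.time_h.min())
    hi = min(curve_a.time_h.max(), curve_b.time_h.max())
    grid = grid[(grid >= lo) & (grid <= hi)]
    diff = pd.DataFrame(
        {"time_h": grid,
         "survival_a": [curve_a.at(t) for t in grid],
         "survival_b": [curve_b.at(t) for t in grid]}
    )
    diff["difference"] = diff["survival_a"] - diff["survival_b"]
    stat = p = None
    if records_a is not None and records_b is not None:
        from lifelines.statistics import logrank_test

        ra, rb = list(records_a), list(records_b)
        res = logrank_test(
            [r.event_time_h for r in ra], [r.event_time_h for r in rb],
            event_observed_A=[1 if r.status == "died" else 0 for r in ra],
            event_observed_B=[1 if r.status == "died" else 0 for r in rb],
        )
        stat, p = float(res.test_statistic), float(res.p_value)
    return CurveComparison(med_a, med_b, sent_a, sent_b, diff, stat, p)


def records_from_death_times(
    death_times: Sequence[float],
    end_time_h: float,
    prefix: str = "w",
) -> list[SurvivalRecord]:
    """Build uncensored records from simulated death times (inf = survives)."""
    recs = []
    for i, dt in enumerate(death_times):
        if math.isfinite(dt) and dt <= end_time_h:
            recs.append(SurvivalRecord(f"{prefix}{i}", float(dt), "died"))
        else:
            recs.append(SurvivalRecord(f"{prefix}{i}", float(end_time_h), "alive_at_end"))
    return recs


def plot_survival(curves, labels=None, ax=None, shade_se: bool = True):
    """Plot one or more survival curves as step functions with SE bands.

    Requires matplotlib; returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    if labels is None:
        labels = [c.method for c in curves]
    for curve, label in zip(curves, labels):
        ax.step(curve.time_h, curve.survival, where="post", label=label)
        if shade_se:
            ax.fill_between(
                curve.time_h,
                np.clip(curve.survival - curve.std_err, 0, 1),
                np.clip(curve.survival + curve.std_err, 0, 1),
                step="post", alpha=0.2,
            )
    ax.set_xlabel("time post infection (h)")
    ax.set_ylabel("survival probability S(t)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False)
    return ax
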