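"""Sub-state kinetics statistics on idealized event tables.

Transition accounting, time-weighted level occupancies, intra-burst
closure analysis (frequency and dwell statistics under the <100 ms burst
closure cutoff and the Oi -> C -> Oi same-level re-entry rule),
exponential dwell fitting with dead-time correction, dwell comparisons,
current--voltage slope-conductance fits, and a chi-square consistency test
of closed-state re-entry against sub-state occupancies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from kirgate.idealization import EventTable


@dataclass
class TransitionMatrix:
    """Counts of ordered level-pair transitions at event boundaries."""

    counts: np.ndarray          # square, diagonal zero
    total_time: float           # s
    level_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be square")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if np.diag(c).any():
            raise ValueError("self-transitions are impossible in an EventTable")
        self.counts = c.astype(int)

    @property
    def total_transitions(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClosureStats:
    """Intra-burst closure summary.

    Undefined statistics (no kept closures) are NaN, never zero.
    """

    frequency: float            # closures per second of analysis time
    mean_dwell: float           # s
    se_dwell: float             # s
    n_closures: int
    selection: str              # description of the rule applied


@dataclass
class IVFit:
    """Per-level slope-conductance fit of the current--voltage relation."""

    slope_pS: float
    intercept_pA: float
    r_squared: float
    voltages_mV: np.ndarray


# ---------------------------------------------------------------------------


def transition_matrix(events: EventTable,
                      n_levels: int | None = None) -> TransitionMatrix:
    """Count ordered level transitions at event boundaries."""
    if len(events) < 2:
        raise ValueError("need at least 2 events")
    lv = events.levels
    if n_levels is None:
        n_levels = int(lv.max()) + 1
    counts = np.zeros((n_levels, n_levels), int)
    np.add.at(counts, (lv[:-1], lv[1:]), 1)
    labels = tuple(["C"] + [f"O{i}" for i in range(1, n_levels)])
    return TransitionMatrix(counts=counts,
                            total_time=events.total_duration,
                            level_labels=labels)


def occupancies(events: EventTable,
                n_levels: int | None = None) -> np.ndarray:
    """Time-weighted occupancy per level (sums to 1)."""
    if events.total_duration <= 0:
        raise ValueError("events cover zero time")
    lv = events.levels
    if n_levels is None:
        n_levels = int(lv.max()) + 1
    occ = np.zeros(n_levels)
    np.add.at(occ, lv, events.durations)
    return occ / occ.sum()


def closure_stats(events: EventTable, burst_cutoff: float = 0.1,
                  same_level_only: bool = True,
                  closed_level: int = 0,
                  per_open_time: bool = False) -> ClosureStats:
    """Frequency and dwell statistics of brief intra-burst closures.

    Closures are closed-level events with duration below ``burst_cutoff``
    (default 100 ms).  With ``same_level_only`` only closures flanked by
    the same conducting level (Oi -> C -> Oi) are kept.  Frequency is
    normalized per second of total analysis time, or per second of open
    time with ``per_open_time``.
    """
    if burst_cutoff <= 0:
        raise ValueError("burst_cutoff must be > 0")
    lv = events.levels
    dur = events.durations
    is_c = lv == closed_level
    keep = is_c & (dur < burst_cutoff)
    if same_level_only:
        flanked = np.zeros(len(events), bool)
        idx = np.flatnonzero(keep)
        inner = idx[(idx > 0) & (idx < len(events) - 1)]
        ok = lv[inner - 1] == lv[inner + 1]
        flanked[inner[ok]] = True
        keep = flanked
    dwells = dur[keep]
    n = int(keep.sum())
    denom = (dur[~is_c].sum() if per_open_time else events.total_duration)
    freq = n / denom if denom > 0 else np.nan
    if n > 0:
        mean = float(dwells.mean())
        se = float(dwells.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    else:
        mean = se = np.nan
    rule = ("Oi->C->Oi, dur < %.3g s" % burst_cutoff if same_level_only
            else "C events, dur < %.3g s" % burst_cutoff)
    return ClosureStats(frequency=freq, mean_dwell=mean, se_dwell=se,
                        n_closures=n, selection=rule)


def dwell_exponential_fit(durations, dead_time: float = 0.0,
                          conf: float = 0.95
                          ) -> tuple[float, tuple[float, float]]:
    """Exponential mean-dwell MLE with optional dead-time correction.

    Durations observed only above ``dead_time`` follow a shifted
    exponential; by memorylessness the MLE of the time constant is
    ``mean(d) - dead_time``.  Returns (tau, normal-approximation CI).
    """
    d = np.asarray(durations, float)
    if len(d) < 5:
        raise ValueError("need at least 5 dwell times")
    if (d <= 0).any():
        raise ValueError("durations must be positive")
    if dead_time < 0:
        raise ValueError("dead_time must be >= 0")
    tau = float(d.mean() - dead_time)
    se = tau / np.sqrt(len(d))
    z = stats.norm.ppf(0.5 + conf / 2)
    return tau, (tau - z * se, tau + z * se)


def compare_dwells(a, b) -> float:
    """Two-sided Welch (unequal-variance) t-test p-value on mean dwells."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 dwells per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 1.0
        raise ValueError("zero variance in both samples")
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def iv_fit(voltages_mV, currents_pA, fix_reversal: bool = False) -> IVFit:
    """OLS fit of current vs voltage; slope in pS (pA/mV * 1000).

    ``fix_reversal`` forces the line through the origin (E_rev = 0 mV).
    """
    v = np.asarray(voltages_mV, float)
    i = np.asarray(currents_pA, float)
    if len(np.unique(v)) < 2:
        raise ValueError("need >= 2 distinct voltages")
    if fix_reversal:
        slope = float(np.dot(v, i) / np.dot(v, v))
        intercept = 0.0
        pred = slope * v
    else:
        slope, intercept = np.polyfit(v, i, 1)
        pred = slope * v + intercept
    ss_res = float(((i - pred) ** 2).sum())
    ss_tot = float(((i - i.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return IVFit(slope_pS=float(slope) * 1000.0,
                 intercept_pA=float(intercept), r_squared=r2,
                 voltages_mV=np.unique(v))


def reentry_consistency(events: EventTable, closed_level: int = 0
                        ) -> tuple[float, float]:
    """Chi-square test: C -> Oi re-entry distribution vs open occupancies.

    If closures at the selectivity filter occur independently of the
    sub-state ladder, the destination of each reopening should follow the
    occupancy distribution of the conducting levels.  Expected counts
    below 1 are pooled with the nearest level.
    """
    lv = events.levels
    dest = lv[1:][lv[:-1] == closed_level]
    dest = dest[dest != closed_level]
    if len(dest) < 20:
        raise ValueError("need >= 20 C->O transitions")
    occ = occupancies(events)
    open_levels = np.array([j for j in range(len(occ))
                            if j != closed_level and occ[j] > 0])
    p_open = occ[open_levels] / occ[open_levels].sum()
    obs = np.array([(dest == j).sum() for j in open_levels], float)
    exp = p_open * len(dest)
    # pool cells with expectation < 1 into the neighbor with larger exp
    while len(exp) > 1 and exp.min() < 1.0:
        i = int(np.argmin(exp))
        j = i - 1 if i > 0 else i + 1
        exp[j] += exp[i]
        obs[j] += obs[i]
        exp = np.delete(exp, i)
        obs = np.delete(obs, i)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    dof = max(len(exp) - 1, 1)
    p = float(stats.chi2.sf(chi2, dof))
    return chi2, p
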