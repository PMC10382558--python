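"""Trace idealization: level discovery and event segmentation.

Single-channel records with sub-conductance gating show multiple stable
current levels between zero and the fully open amplitude.  This module
recovers them in three steps:

1. all-point amplitude histogram (every sample of the trace),
2. level discovery from smoothed histogram peaks, refined by 1-D
   mean/variance re-estimation, with the zero (closed) level anchored at
   0 pA (records are baseline-subtracted),
3. Viterbi segmentation under per-level Gaussian emissions and a uniform
   off-diagonal transition prior, followed by dead-time censoring of
   events too brief to be resolved through the low-pass filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from kirgate.gating_simulator import Trace


@dataclass
class LevelSet:
    """Discrete conductance levels of a trace.

    ``currents`` includes 0 pA for the closed level and is sorted by
    absolute amplitude; ``sds`` are per-level noise standard deviations.
    """

    currents: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        self.currents = np.asarray(self.currents, float)
        self.sds = np.asarray(self.sds, float)
        order = np.argsort(np.abs(self.currents), kind="stable")
        self.currents = self.currents[order]
        self.sds = self.sds[order]
        if abs(self.currents[0]) > 1e-9:
            raise ValueError("LevelSet must include the zero (closed) level")

    @property
    def n_levels(self) -> int:
        return len(self.currents)

    @property
    def relative(self) -> np.ndarray:
        return relative_amplitudes(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"currents_pA": self.currents.tolist(),
                       "sds_pA": self.sds.tolist()}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "LevelSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["currents_pA"]), np.asarray(d["sds_pA"]))


class EventTable:
    """Idealized event sequence: (level index, start, duration, mean pA).

    Level indices refer to a LevelSet ordered by |current| (0 = closed).
    Events tile the trace contiguously and consecutive events differ in
    level.
    """

    COLUMNS = ("level", "start_s", "duration_s", "mean_pA")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"EventTable missing columns {sorted(missing)}")
        if (df["duration_s"] <= 0).any():
            raise ValueError("event durations must be > 0")
        lv = df["level"].to_numpy()
        if len(lv) > 1 and (lv[1:] == lv[:-1]).any():
            raise ValueError("consecutive events must differ in level")
        self.df = df.reset_index(drop=True)

    @property
    def levels(self) -> np.ndarray:
        return self.df["level"].to_numpy(int)

    @property
    def starts(self) -> np.ndarray:
        return self.df["start_s"].to_numpy(float)

    @property
    def durations(self) -> np.ndarray:
        return self.df["duration_s"].to_numpy(float)

    @property
    def mean_currents(self) -> np.ndarray:
        return self.df["mean_pA"].to_numpy(float)

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EventTable":
        return cls(pd.read_csv(path))

    @classmethod
    def from_arrays(cls, levels, starts, durations,
                    mean_currents=None) -> "EventTable":
        if mean_currents is None:
            mean_currents = np.full(len(levels), np.nan)
        return cls(pd.DataFrame({
            "level": np.asarray(levels, int),
            "start_s": np.asarray(starts, float),
            "duration_s": np.asarray(durations, float),
            "mean_pA": np.asarray(mean_currents, float)}))


# ---------------------------------------------------------------------------
# operations


def allpoint_histogram(trace: Trace, bin_width: float = 0.1
                       ) -> tuple[np.ndarray, np.ndarray]:
    """All-point amplitude histogram (bin centers, counts)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    x = np.asarray(trace.current, float)
    if x.size == 0:
        raise ValueError("empty trace")
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    counts, edges = np.histogram(x, bins=n_bins, range=(lo, lo + n_bins * bin_width))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts


def _em_1d(x: np.ndarray, means: np.ndarray, sigma: float,
           counts: np.ndarray | None = None,
           n_iter: int = 200, fix_zero: bool = True,
           fit_sigma: bool = False,
           tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, float]:
    """Tied-variance 1-D Gaussian-mixture EM with an anchored zero mean.

    ``x`` may be raw samples or (with ``counts``) fine histogram bin
    centers, in which case the EM is count-weighted.  Returns (means,
    weights, sigma).  The component closest to 0 keeps its mean at
    exactly 0 when ``fix_zero`` (baseline-subtracted records).  With
    ``fit_sigma`` False the common sigma stays at the supplied value (the
    measured noise scale); fixing it prevents unmodelled mass from
    inflating sigma and washing out close level pairs.
    """
    means = means.astype(float).copy()
    m = len(means)
    c = (np.ones(len(x)) if counts is None
         else np.asarray(counts, float))
    n_tot = c.sum()
    w = np.full(m, 1.0 / m)
    sigma = max(sigma, 1e-6)
    zero_j = int(np.argmin(np.abs(means))) if fix_zero else -1
    prev = -np.inf
    for _ in range(n_iter):
        z = (x[:, None] - means[None, :]) / sigma
        logp = -0.5 * z ** 2 - np.log(sigma) + np.log(np.maximum(w, 1e-300))
        mx = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - mx)
        norm = p.sum(axis=1, keepdims=True)
        r = p / norm * c[:, None]
        ll = float((c * (np.log(norm[:, 0]) + mx[:, 0])).sum())
        nk = r.sum(axis=0)
        w = nk / n_tot
        upd = nk > 0
        means[upd] = (r[:, upd] * x[:, None]).sum(axis=0) / nk[upd]
        if fix_zero:
            means[zero_j] = 0.0
        if fit_sigma:
            var = (r * (x[:, None] - means[None, :]) ** 2).sum() / n_tot
            sigma = max(np.sqrt(var), 1e-6)
        if abs(ll - prev) < tol * (1 + abs(ll)):
            break
        prev = ll
    return means, w, sigma


def estimate_noise_sd(trace: Trace) -> float:
    """Baseline noise sd from robust first differences.

    Within a constant level, successive differences have variance
    ``2 sigma^2 (1 - rho1)`` with ``rho1`` the lag-1 autocorrelation of
    the filtered noise, computable from the known acquisition filter; the
    median absolute deviation makes the estimate insensitive to the rare
    large differences at level transitions.
    """
    x = np.asarray(trace.current, float)
    d = np.diff(x)
    sd_d = 1.4826 * np.median(np.abs(d - np.median(d)))
    acq = trace.acquisition
    if acq.filter_corner:
        from kirgate.gating_simulator import bessel_lowpass_sos
        imp = np.zeros(4096)
        imp[2048] = 1.0
        h = signal.sosfiltfilt(
            bessel_lowpass_sos(acq.filter_corner, acq.sample_rate), imp)
        rho1 = float(np.dot(h[:-1], h[1:]) / np.dot(h, h))
    else:
        rho1 = 0.0
    return max(sd_d / np.sqrt(2.0 * (1.0 - rho1)), 1e-6)


def detect_levels(trace: Trace, expected_max_levels: int = 5,
                  min_separation: float = 0.4,
                  bin_width: float = 0.1,
                  smooth_bins: float = 1.5,
                  min_weight: float = 1e-3) -> LevelSet:
    """Find conductance levels from the all-point histogram.

    The baseline noise scale is measured from robust first differences
    and held fixed; a tied, fixed-sigma 1-D Gaussian-mixture EM on the
    samples is grown greedily: starting from the smoothed-histogram
    peaks, new components are added where the fitted mixture leaves the
    most unexplained histogram mass (levels hidden as shoulders never
    show up as separate peaks), up to ``expected_max_levels``.
    Components closer than ``min_separation`` or lighter than
    ``min_weight`` merge into their nearest neighbor; the zero (closed)
    level is anchored at 0 pA.
    """
    if expected_max_levels < 2:
        raise ValueError("expected_max_levels must be >= 2")
    x = np.asarray(trace.current, float)
    sigma = estimate_noise_sd(trace)
    # run the EM on a finely binned histogram (count-weighted): with bins
    # much narrower than the noise sd this is statistically equivalent to
    # raw samples and independent of trace length
    fine_bw = max(min(bin_width, sigma / 5.0), 1e-4)
    fine_edges = np.arange(x.min() - fine_bw, x.max() + 2 * fine_bw, fine_bw)
    fine_counts, fine_edges = np.histogram(x, bins=fine_edges)
    x_em = 0.5 * (fine_edges[:-1] + fine_edges[1:])
    keep_bins = fine_counts > 0
    x_em, c_em = x_em[keep_bins], fine_counts[keep_bins].astype(float)
    centers, counts = allpoint_histogram(trace, bin_width)
    smooth = ndimage.gaussian_filter1d(counts.astype(float), smooth_bins)
    min_dist = max(1, int(round(min_separation / bin_width)))
    peaks, _ = signal.find_peaks(
        smooth, distance=min_dist,
        prominence=0.01 * smooth.max() if smooth.max() > 0 else None)
    cand = centers[peaks]
    heights = smooth[peaks].astype(float)
    keep = np.abs(cand) > min_separation / 2
    cand, heights = cand[keep], heights[keep]
    if len(cand) == 0:
        raise ValueError(
            "no resolvable non-zero level: histogram has no peak away "
            "from baseline; check noise level or min_separation")
    order = np.argsort(heights)[::-1][: expected_max_levels - 1]
    means = np.concatenate([[0.0], np.sort(cand[order])])

    def _merge(means, w):
        means, w = means.copy(), w.copy()
        changed = True
        while changed and len(means) > 1:
            changed = False
            order = np.argsort(means)
            means, w = means[order], w[order]
            zero_j = int(np.argmin(np.abs(means)))
            gaps = np.diff(means)
            i = int(np.argmin(gaps))
            if gaps[i] < min_separation:
                tot = w[i] + w[i + 1]
                if zero_j in (i, i + 1):
                    mu = 0.0
                else:
                    mu = ((means[i] * w[i] + means[i + 1] * w[i + 1]) / tot
                          if tot > 0 else 0.5 * (means[i] + means[i + 1]))
                means[i], w[i] = mu, tot
                means = np.delete(means, i + 1)
                w = np.delete(w, i + 1)
                changed = True
                continue
            light = [j for j in range(len(means))
                     if w[j] < min_weight and j != zero_j]
            if light:
                j = light[0]
                k = j - 1 if (j == len(means) - 1 or
                              (j > 0 and gaps[j - 1] < gaps[j])) else j + 1
                w[k] += w[j]
                means = np.delete(means, j)
                w = np.delete(w, j)
                changed = True
        return means, w

    # greedy mixture growth at fixed noise sigma
    bump_sd = np.hypot(sigma, bin_width * smooth_bins)
    scale = len(x) * bin_width / (bump_sd * np.sqrt(2 * np.pi))
    w = None
    for _ in range(expected_max_levels + 2):
        means, w, _ = _em_1d(x_em, means, sigma, counts=c_em)
        means, w = _merge(means, w)
        if len(means) >= expected_max_levels:
            break
        dens = scale * (
            w[None, :] * np.exp(-0.5 * ((centers[:, None] - means[None, :])
                                        / bump_sd) ** 2)).sum(axis=1)
        resid = smooth - dens
        resid[np.abs(centers) < min_separation / 2] = 0.0
        j = int(np.argmax(resid))
        if resid[j] <= 0.005 * smooth.max():
            break
        means = np.concatenate([means, [centers[j]]])
    means, w, _ = _em_1d(x_em, means, sigma, counts=c_em)
    means, w = _merge(means, w)
    # one soft E/M pass on the raw samples removes the fine-bin
    # quantization from the reported means
    means, w, _ = _em_1d(x, means, sigma, n_iter=1)
    means, w = _merge(means, w)
    return LevelSet(currents=means, sds=np.full(len(means), sigma))


def _viterbi_decode(x: np.ndarray, means: np.ndarray, sds: np.ndarray,
                    p_stay: float = 0.999) -> np.ndarray:
    """Most likely level path under Gaussian emissions.

    Uniform off-diagonal transition prior: stay probability ``p_stay``,
    the remainder split equally over the other levels.  Decoding is done
    with hmmlearn's GaussianHMM (parameters set, not fitted).
    """
    from hmmlearn.hmm import GaussianHMM

    m = len(means)
    if m == 1:
        return np.zeros(len(x), dtype=int)
    model = GaussianHMM(n_components=m, covariance_type="diag",
                        init_params="", params="")
    model.startprob_ = np.full(m, 1.0 / m)
    off = (1.0 - p_stay) / (m - 1)
    model.transmat_ = np.full((m, m), off)
    np.fill_diagonal(model.transmat_, p_stay)
    model.means_ = means.reshape(-1, 1)
    model.covars_ = np.maximum(sds, 1e-9).reshape(-1, 1) ** 2
    _, path = model.decode(x.reshape(-1, 1), algorithm="viterbi")
    return path


def _runs(path: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(level, start index, run length) of maximal constant runs."""
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [len(path)]]))
    return path[starts], starts, lengths


def idealize(trace: Trace, levels: LevelSet,
             dead_time: float = 0.5e-3,
             p_stay: float = 0.999) -> EventTable:
    """Segment a trace into an EventTable over a LevelSet.

    Viterbi assignment under Gaussian emissions; events shorter than
    ``dead_time`` are merged into the neighboring event whose level is
    nearest in current; event mean currents are recomputed from the raw
    samples.
    """
    if levels.n_levels == 0:
        raise ValueError("empty LevelSet")
    fs = trace.acquisition.sample_rate
    if dead_time < 1.0 / fs:
        raise ValueError("dead_time must be >= one sample interval")
    x = np.asarray(trace.current, float)
    # emission width reflects THIS trace's noise: on a cleaner signal
    # (e.g. a reconstructed ideal trace) the stored level sds would let
    # the stay-prior swallow genuine short events
    sds = np.minimum(levels.sds, max(estimate_noise_sd(trace), 1e-9))
    path = _viterbi_decode(x, levels.currents, sds, p_stay)

    dead_samples = max(1, int(round(dead_time * fs)))
    lv, starts, lengths = _runs(path)
    # iteratively merge sub-dead-time runs into the closer-current neighbor
    changed = True
    while changed and len(lv) > 1:
        changed = False
        short = np.flatnonzero(lengths < dead_samples)
        if len(short) == 0:
            break
        i = int(short[np.argmin(lengths[short])])
        if i == 0:
            j = 1
        elif i == len(lv) - 1:
            j = i - 1
        else:
            di = abs(levels.currents[lv[i - 1]] - levels.currents[lv[i]])
            dj = abs(levels.currents[lv[i + 1]] - levels.currents[lv[i]])
            j = i - 1 if di <= dj else i + 1
        # absorb run i into neighbor j
        if j < i:
            lengths[j] += lengths[i]
        else:
            lengths[j] += lengths[i]
            starts[j] = starts[i]
        lv = np.delete(lv, i)
        starts = np.delete(starts, i)
        lengths = np.delete(lengths, i)
        # merge neighbors that now share a level
        k = 0
        while k < len(lv) - 1:
            if lv[k] == lv[k + 1]:
                lengths[k] += lengths[k + 1]
                lv = np.delete(lv, k + 1)
                starts = np.delete(starts, k + 1)
                lengths = np.delete(lengths, k + 1)
            else:
                k += 1
        changed = True

    means = np.array([x[s:s + n].mean() for s, n in zip(starts, lengths)])
    return EventTable.from_arrays(levels=lv, starts=starts / fs,
                                  durations=lengths / fs,
                                  mean_currents=means)


def relative_amplitudes(levels: LevelSet) -> np.ndarray:
    """Level currents normalized by the largest |current| (top level = 1)."""
    a = np.abs(levels.currents)
    top = a.max()
    if top == 0:
        raise ValueError("all levels are zero; no top level to normalize by")
    return a / top
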