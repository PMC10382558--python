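"""Stochastic single-channel trace simulator.

Generates synthetic patch-clamp data from the per-subunit protonation
gating model: a continuous-time Markov chain over states ``(k, open)`` and
``(k, closed)`` (k = number of protonated sites) is sampled exactly
(Gillespie), and the resulting piecewise-constant ideal current is rendered
with Gaussian noise and a digital Bessel-type low-pass filter emulating the
acquisition chain (3 kHz sampling, 1 kHz 4-pole filter by default).

Kinetics follow the diffusion-limited protonation picture: with
k_on ~ 1e10 M^-1 s^-1 and a cavity-upshifted pKa near 7 (K_H ~ 2e-7 M),
both k_on*[H+] and k_off = k_on*K_H land near 1e3 s^-1 at neutral pH, so
sub-state dwells are in the millisecond range; the pKa shift is carried
entirely by K_H.  ``rate_scale`` (default 1) uniformly slows or speeds the
protonation kinetics, e.g. to generate recordings whose sub-state dwells
are long relative to the acquisition bandwidth.

A second, empirical generator (:func:`simulate_occupancy_trace`) builds a
semi-Markov level sequence realizing a prescribed stationary occupancy
vector with a nearest-level-biased transition kernel, for recovery tests
parameterized directly by measured occupancies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from kirgate.protonation_model import ModelParams, state_distribution


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the gating chain.

    ``k_on`` is the per-site protonation rate constant (M^-1 s^-1,
    diffusion-limited by default), multiplied by ``rate_scale``; per-site
    ``k_off = k_on_eff * K_H``.  ``lambda_c`` is the open->brief-closed
    rate and ``tau_c`` the mean brief-closed dwell; their product
    ``lambda_c * tau_c`` equals the equilibrium constant K_OC at detailed
    balance.
    """

    model: ModelParams
    k_on: float = 1e10
    rate_scale: float = 1.0
    lambda_c: float = 3.7
    tau_c: float = 6.4e-3

    def __post_init__(self) -> None:
        for name in ("k_on", "rate_scale", "lambda_c", "tau_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def k_on_eff(self) -> float:
        return self.k_on * self.rate_scale


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition chain settings (defaults: 3 kHz sampling, 1 kHz filter)."""

    sample_rate: float = 3000.0
    filter_corner: float = 1000.0
    noise_sd: float = 0.42       # pre-filter white noise, pA
    voltage: float = -120.0      # mV
    reversal: float = 0.0        # mV
    full_conductance: float = 60.0  # pS
    pH: float = 7.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.filter_corner and \
                self.sample_rate <= 2.0 * self.filter_corner * 0.9:
            raise ValueError(
                f"sample_rate {self.sample_rate} too low for filter corner "
                f"{self.filter_corner}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class StatePath:
    """Piecewise-constant state trajectory.

    ``states`` holds (k, is_open) ids; ``entry_times`` and ``dwells`` are in
    seconds, contiguous from 0.
    """

    states: list[tuple[int, bool]]
    entry_times: np.ndarray
    dwells: np.ndarray

    def __post_init__(self) -> None:
        self.entry_times = np.asarray(self.entry_times, float)
        self.dwells = np.asarray(self.dwells, float)
        if (self.dwells <= 0).any():
            raise ValueError("dwells must be > 0")

    @property
    def duration(self) -> float:
        return float(self.entry_times[-1] + self.dwells[-1])

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "k": [s[0] for s in self.states],
            "open": [int(s[1]) for s in self.states],
            "entry_s": self.entry_times,
            "dwell_s": self.dwells,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StatePath":
        df = pd.read_csv(path)
        return cls(states=[(int(k), bool(o))
                           for k, o in zip(df["k"], df["open"])],
                   entry_times=df["entry_s"].to_numpy(),
                   dwells=df["dwell_s"].to_numpy())


@dataclass
class Trace:
    """A sampled current trace with its ground truth.

    ``current`` is the noisy, filtered signal; ``ideal_current`` the
    noiseless piecewise-constant truth (both pA, sampled uniformly).
    """

    times: np.ndarray
    current: np.ndarray
    ideal_current: np.ndarray
    acquisition: AcquisitionParams
    true_path: StatePath | None = None
    true_levels: np.ndarray | None = None  # per-sample true level index

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.current)
                == len(self.ideal_current)):
            raise ValueError("times/current/ideal_current length mismatch")

    @property
    def duration(self) -> float:
        return len(self.times) / self.acquisition.sample_rate

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "current_pA": self.current}
                     ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, acquisition: AcquisitionParams) -> "Trace":
        df = pd.read_csv(path)
        cur = df["current_pA"].to_numpy(float)
        return cls(times=df["time_s"].to_numpy(float), current=cur,
                   ideal_current=np.full_like(cur, np.nan),
                   acquisition=acquisition)


# ---------------------------------------------------------------------------
# rate matrix


class Generator:
    """Transition-rate specification over states {(k, O), (k, C)}.

    States are indexed ``2*k`` (open) and ``2*k + 1`` (brief closed),
    k = 0..N.  The rate matrix Q has rows summing to 0.
    """

    def __init__(self, Q: np.ndarray, n_sites: int):
        self.Q = Q
        self.n_sites = n_sites
        self.n_states = Q.shape[0]

    def state_id(self, k: int, is_open: bool) -> int:
        return 2 * k + (0 if is_open else 1)

    def decode(self, idx: int) -> tuple[int, bool]:
        return idx // 2, idx % 2 == 0

    def stationary(self) -> np.ndarray:
        """Stationary distribution by null-space solve of Q^T."""
        A = np.vstack([self.Q.T, np.ones(self.n_states)])
        b = np.zeros(self.n_states + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 0, None)
        return pi / pi.sum()


def build_generator(kp: KineticParams, pH: float | None = None) -> Generator:
    """Rate matrix of the protonation/closure chain at one pH.

    Protonation from (k, .) proceeds at ``(N-k) * k_on_eff * [H+]``,
    deprotonation at ``k * k_off`` with ``k_off = k_on_eff * K_H``;
    closures (rate ``lambda_c``) and reopenings (rate ``1/tau_c``) are
    independent of k, and protonation continues during closed sojourns.
    """
    model = kp.model
    if len(model.site_classes) != 1 and model.n_total > 0:
        raise ValueError("kinetic simulation supports a single site class")
    N = model.n_total
    K_H = model.site_classes[0].K_H if model.site_classes else 1e-7
    if pH is None:
        raise ValueError("pH required to build the generator")
    h = 10.0 ** (-pH)
    kon = kp.k_on_eff * h          # per-site protonation propensity, s^-1
    koff = kp.k_on_eff * K_H       # per-site deprotonation, s^-1

    n_states = 2 * (N + 1)
    Q = np.zeros((n_states, n_states))
    for k in range(N + 1):
        for is_open in (True, False):
            i = 2 * k + (0 if is_open else 1)
            if k < N:
                Q[i, 2 * (k + 1) + (0 if is_open else 1)] = (N - k) * kon
            if k > 0:
                Q[i, 2 * (k - 1) + (0 if is_open else 1)] = k * koff
            if is_open:
                if kp.lambda_c > 0:
                    Q[i, i + 1] = kp.lambda_c
            else:
                if kp.tau_c > 0:
                    Q[i, i - 1] = 1.0 / kp.tau_c
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Generator(Q, N)


def simulate_path(generator: Generator, duration: float,
                  seed: int | np.random.Generator = 0,
                  initial_state: int | None = None) -> StatePath:
    """Exact (Gillespie) sample of the chain for ``duration`` seconds."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    Q = generator.Q
    n = generator.n_states
    if initial_state is None:
        initial_state = int(np.argmax(generator.stationary()))
    states, entries, dwells = [], [], []
    t, s = 0.0, initial_state
    while t < duration:
        exit_rate = -Q[s, s]
        if exit_rate <= 0:
            dwell = duration - t  # absorbing
        else:
            dwell = rng.exponential(1.0 / exit_rate)
        dwell = min(dwell, duration - t)
        states.append(generator.decode(s))
        entries.append(t)
        dwells.append(dwell)
        t += dwell
        if t >= duration:
            break
        rates = Q[s].copy()
        rates[s] = 0.0
        s = int(rng.choice(n, p=rates / rates.sum()))
    return StatePath(states=states, entry_times=np.array(entries),
                     dwells=np.array(dwells))


# ---------------------------------------------------------------------------
# rendering


def bessel_lowpass_sos(corner_hz: float, sample_rate: float) -> np.ndarray:
    """4-pole Bessel low-pass, -3 dB at ``corner_hz`` (digital, bilinear)."""
    return signal.bessel(4, corner_hz, btype="low", norm="mag",
                         fs=sample_rate, output="sos")


def _sample_ideal(path: StatePath, sample_rate: float,
                  level_of_state) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample level index and segment boundaries at ``sample_rate``."""
    n_samples = int(round(path.duration * sample_rate))
    t = np.arange(n_samples) / sample_rate
    edges = np.concatenate([path.entry_times,
                            [path.entry_times[-1] + path.dwells[-1]]])
    seg = np.clip(np.searchsorted(edges, t, side="right") - 1, 0,
                  len(path.states) - 1)
    levels = np.array([level_of_state(s) for s in path.states])
    return t, levels[seg]


def render_trace(path: StatePath, acq: AcquisitionParams,
                 conductance_map: dict[int, float] | None = None,
                 seed: int | np.random.Generator | None = None) -> Trace:
    """Render a StatePath as a sampled, noisy, filtered current trace.

    Ideal current is ``i = g(k) * (V - E_rev)`` with
    ``g(k) = full_conductance * conductance_map[k]`` (pS), zero when
    closed; with conductance in pS and potentials in mV the current is
    ``g * V / 1000`` pA (60 pS at -120 mV gives -7.2 pA).  White Gaussian
    noise (sd ``noise_sd``) is added before the 4-pole Bessel-type digital
    low-pass at ``filter_corner``.
    """
    if conductance_map is None:
        from kirgate.protonation_model import _default_conductance_map
        n = max(k for k, _ in path.states)
        conductance_map = _default_conductance_map(max(n, 4))
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(acq.seed if seed is None else seed))

    drive_mV = acq.voltage - acq.reversal

    def amp(state: tuple[int, bool]) -> float:
        k, is_open = state
        if not is_open:
            return 0.0
        return conductance_map[k] * acq.full_conductance * drive_mV / 1000.0

    t, ideal = _sample_ideal(path, acq.sample_rate, amp)
    current = ideal.astype(float).copy()
    if acq.noise_sd > 0:
        current = current + rng.normal(0.0, acq.noise_sd, size=len(current))
    if acq.filter_corner:
        sos = bessel_lowpass_sos(acq.filter_corner, acq.sample_rate)
        current = signal.sosfiltfilt(sos, current)

    # per-sample true level index: 0 = closed, then by |amplitude| ascending
    amps = sorted({amp(s) for s in path.states} | {0.0}, key=abs)
    level_idx = {a: i for i, a in enumerate(amps)}
    _, true_amp = _sample_ideal(path, acq.sample_rate, amp)
    true_levels = np.array([level_idx[a] for a in true_amp])

    return Trace(times=t, current=current, ideal_current=ideal,
                 acquisition=acq, true_path=path, true_levels=true_levels)


# ---------------------------------------------------------------------------
# empirical occupancy-parameterized generator


def _occupancy_kernel(target: np.ndarray,
                      adjacency_bias: float = 8.0,
                      closed_index: int | None = None) -> np.ndarray:
    """Nearest-level-biased jump kernel with the requested stationary vector.

    A Metropolis-Hastings kernel over levels with symmetric proposal
    weights ``w_ij = bias^(1-|i-j|)`` (adjacent moves preferred) and a
    common row normalizer; the remainder goes to the diagonal.  Detailed
    balance with respect to ``target`` holds exactly; self-transitions
    only lengthen sojourns and do not appear as level transitions.

    The closed level (``closed_index``) sits outside the conducting
    ladder: closures strike from, and reopen to, any conducting level
    (proposal weight 1), mirroring their independence from the sub-state
    ladder.
    """
    nu = np.asarray(target, float)
    m = len(nu)
    W = np.zeros((m, m))
    for i in range(m):
        if nu[i] == 0:
            continue
        for j in range(m):
            if i != j and nu[j] > 0:
                if closed_index is not None and closed_index in (i, j):
                    W[i, j] = 1.0
                else:
                    W[i, j] = adjacency_bias ** (1 - abs(i - j))
    norm = W.sum(axis=1).max()
    P = np.zeros((m, m))
    for i in range(m):
        if nu[i] == 0:
            continue
        for j in range(m):
            if i != j and nu[j] > 0:
                P[i, j] = W[i, j] / norm * min(1.0, nu[j] / nu[i])
        P[i, i] = 1.0 - P[i].sum()
    return P


def simulate_occupancy_trace(levels, occupancies, acq: AcquisitionParams,
                             mean_dwells=0.020,
                             seed: int | np.random.Generator | None = None,
                             duration: float = 300.0,
                             adjacency_bias: float = 8.0) -> Trace:
    """Semi-Markov trace realizing a target stationary occupancy vector.

    ``levels`` are relative amplitudes (fractions of the full level; 0 for
    the closed level) and ``occupancies`` the target time-weighted
    stationary probabilities, in matching order.  Jumps prefer adjacent
    levels; per-level mean dwells are scaled so that the time-weighted
    occupancies converge to the target as duration grows.
    """
    levels = np.asarray(levels, float)
    pi = np.asarray(occupancies, float)
    if len(levels) != len(pi):
        raise ValueError("levels and occupancies must have equal length")
    if abs(pi.sum() - 1.0) > 1e-6:
        raise ValueError(f"occupancies must sum to 1, got {pi.sum()}")
    mean_dwells = np.broadcast_to(np.asarray(mean_dwells, float),
                                  pi.shape).copy()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(acq.seed if seed is None else seed))

    # Time-weighted occupancy of a semi-Markov chain is nu_i * dwell_i (up
    # to normalization) with nu the embedded jump chain's stationary
    # vector, so the kernel targets nu_i prop pi_i / dwell_i.
    with np.errstate(divide="ignore", invalid="ignore"):
        nu = np.where(pi > 0, pi / mean_dwells, 0.0)
    nu = nu / nu.sum()
    closed = np.flatnonzero(levels == 0)
    P = _occupancy_kernel(nu, adjacency_bias,
                          closed_index=int(closed[0]) if len(closed) else None)
    active = np.flatnonzero(pi > 0)
    if len(active) == 0:
        raise ValueError("all occupancies zero")
    if len(active) > 1:
        offdiag = P[np.ix_(active, active)].copy()
        np.fill_diagonal(offdiag, 0.0)
        if (offdiag.sum(axis=1) == 0).any():
            raise ValueError("stationary vector unreachable with this kernel")
    kernel_pi = nu

    drive = acq.full_conductance * (acq.voltage - acq.reversal) / 1000.0
    amps = levels * drive

    # jump-chain simulation; consecutive identical states (MH rejections)
    # merge into one segment
    state = int(rng.choice(len(pi), p=kernel_pi))
    states_seq, entries, dwells = [], [], []
    t = 0.0
    while t < duration:
        dwell = rng.exponential(mean_dwells[state])
        dwell = min(dwell, duration - t)
        if dwell <= 0:
            break
        if states_seq and states_seq[-1] == state:
            dwells[-1] += dwell
        else:
            states_seq.append(state)
            entries.append(t)
            dwells.append(dwell)
        t += dwell
        if t >= duration:
            break
        state = int(rng.choice(len(pi), p=P[state]))

    path = StatePath(states=[(s, levels[s] != 0) for s in states_seq],
                     entry_times=np.array(entries), dwells=np.array(dwells))
    n_samples = int(round(path.duration * acq.sample_rate))
    tgrid = np.arange(n_samples) / acq.sample_rate
    edges = np.concatenate([path.entry_times, [path.duration]])
    seg = np.clip(np.searchsorted(edges, tgrid, side="right") - 1, 0,
                  len(states_seq) - 1)
    lvl_per_sample = np.array(states_seq)[seg]
    ideal = amps[lvl_per_sample]
    current = ideal.copy()
    if acq.noise_sd > 0:
        current = current + rng.normal(0.0, acq.noise_sd, size=len(current))
    if acq.filter_corner:
        sos = bessel_lowpass_sos(acq.filter_corner, acq.sample_rate)
        current = signal.sosfiltfilt(sos, current)
    order = np.argsort(np.abs(amps), kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return Trace(times=tgrid, current=current, ideal_current=ideal,
                 acquisition=acq, true_path=path,
                 true_levels=rank[lvl_per_sample])


def path_to_events(path: StatePath, conductance_map: dict[int, float],
                   acq: AcquisitionParams):
    """Exact ground-truth EventTable of a StatePath.

    Levels are indexed as in idealization output: 0 for closed, then by
    increasing |current|; consecutive segments on the same level merge.
    """
    from kirgate.idealization import EventTable

    drive = acq.full_conductance * (acq.voltage - acq.reversal) / 1000.0
    amp = {s: (conductance_map[s[0]] * drive if s[1] else 0.0)
           for s in set(path.states)}
    uniq = sorted({a for a in amp.values()} | {0.0}, key=abs)
    idx = {a: i for i, a in enumerate(uniq)}
    levels, starts, durs, means = [], [], [], []
    for s, t0, dw in zip(path.states, path.entry_times, path.dwells):
        li = idx[amp[s]]
        if levels and levels[-1] == li:
            durs[-1] += dw
        else:
            levels.append(li)
            starts.append(t0)
            durs.append(dw)
            means.append(amp[s])
    return EventTable.from_arrays(levels, starts, durs, means)
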