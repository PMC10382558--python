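# Methods

## The gating model

A Kir2 channel with an engineered acidic residue near the helix bundle
crossing is modeled as N independent titratable sites (N = 4 for the
homotetramer; the two-class generalization, e.g. engineered plus native
cavity aspartates or tandem-dimer constructs with fewer ionizable
subunits, takes the convolution of per-class binomials). With per-site
proton occupancy

    f(pH) = [H+] / ([H+] + K_H),     [H+] = 10^(-pH) mol/L,

the number of protonated subunits k is Binomial(N, f), each k defines one
conducting level through a non-increasing relative-conductance map g(k),
and every open level exchanges with a brief-closed partner with
dimensionless equilibrium constant K_OC, independent of k. The state
probabilities are therefore

    P(k, open)   = C(N,k) f^k (1-f)^(N-k) / (1 + K_OC)
    P(k, closed) = P(k, open) * K_OC.

K_H is treated as a molar dissociation constant (pKa = -log10 K_H ≈ 6.7
for the default 2e-7 M); that sign convention is what makes occupancy
shift toward protonated (lower-conductance) states as pH falls.

Only the four levels 1.00 / 0.92 / 0.74 / 0.45 are experimentally
resolvable; the two least-protonated states are not distinguishable and
are merged into the top experimental level. The default conductance map
therefore assigns k = 0 and k = 1 the same relative amplitude (1.0), and
the default aggregation maps k = 0,1 → O4, k = 2 → O3, k = 3 → O2,
k = 4 → O1, with all brief-closed states pooled into C.

Titration fitting minimizes the weighted sum of squared occupancy
residuals over a (pH × level) table, with K_H (per class) and K_OC
optimized on a log10 scale (Levenberg–Marquardt). Least squares on
occupancies, rather than a multinomial likelihood, matches how occupancy
fractions are compared in practice; weights default to 1. Degenerate
tables (identical rows) and underdetermined fits raise; non-convergence
is flagged on the result.

## Kinetics and the simulator

The kinetic chain runs over states (k, open/closed). Protonation from
(k, ·) has propensity (N−k)·k_on·[H+], deprotonation k·k_off with
k_off = k_on·K_H, closure rate λ_c from any open state, reopening rate
1/τ_c, and protonation continues during closed sojourns (closures are
treated as a distinct, independent gate, most likely at the selectivity
filter). Detailed balance holds on the protonation ladder, and the
chain's stationary law equals the equilibrium model exactly when
λ_c·τ_c = K_OC — the pipeline derives τ_c from K_OC by default for that
reason. Paths are sampled exactly (Gillespie); every stage is a pure
function of its seed.

With a diffusion-limited k_on ≈ 1e10 M⁻¹s⁻¹ and the cavity-upshifted pKa
(K_H ≈ 2e-7 M), both k_on·[H+] and k_off land near 1e3 s⁻¹ at neutral
pH, i.e. sub-millisecond to millisecond sub-state dwells. Such dwells are
at the edge of what a 3 kHz / 1 kHz acquisition chain resolves, so the
pipeline's default `rate_scale = 3e-3` slows the ladder uniformly,
producing records whose sub-state dwells (tens of ms) are comfortably
resolvable — the regime in which occupancy recovery is meaningful. The
physical default in `KineticParams` remains `rate_scale = 1`.

Rendering: ideal current i = g(k)·G·(V−E_rev)/1000 pA (G in pS, V in mV;
60 pS at −120 mV gives −7.2 pA), white Gaussian noise added before a
4-pole Bessel-type digital low-pass (−3 dB at the 1 kHz corner,
zero-phase), sampled at 3 kHz. The default pre-filter noise sd (0.42 pA)
leaves a post-filter RMS ≈ 0.32 pA, visually comparable to real records;
no 1/f or seal noise is modeled.

The empirical generator `simulate_occupancy_trace` realizes a prescribed
stationary occupancy vector π with a Metropolis–Hastings jump kernel:
conducting levels propose moves with weights bias^(1−|Δ|) (adjacent moves
preferred, bias = 8), while the closed level couples to every conducting
level with weight 1 — closures strike from and return to any sub-state,
mirroring their independence from the ladder. The kernel targets
ν ∝ π/dwell so the time-weighted occupancies converge to π for any
per-level mean dwells. Mean dwell defaults to 20 ms: the occupancy
targets do not pin a dwell scale, and 20 ms keeps events well resolved at
the 1 kHz bandwidth while leaving thousands of transitions per minute.

## Idealization

Level discovery works on the all-point histogram. The baseline noise sd
is estimated from robust first differences (MAD, corrected for the lag-1
autocorrelation of the known acquisition filter) and then held fixed in
a tied-variance 1-D Gaussian-mixture EM whose zero (closed) component is
anchored at 0 pA (records are baseline-subtracted). The mixture is grown
greedily: seeds come from smoothed-histogram peaks, and new components
are added where the fitted mixture leaves the most unexplained histogram
mass — levels hidden as shoulders (e.g. the 0.92 level next to 1.00 at
realistic noise) never appear as separate peaks, and fitting sigma
instead of fixing it lets unmodeled mass inflate it and wash such pairs
out. Components closer than `min_separation` (default 0.4 pA) or lighter
than 1e-3 merge into their nearest neighbor. The EM runs on a finely
binned, count-weighted histogram (bins ≪ noise sd), making its cost
independent of trace length; a final single E/M pass on the raw samples
removes the bin quantization from the reported means.

Segmentation is a Viterbi decode under Gaussian emissions with a uniform
off-diagonal transition prior (stay probability 0.999). The emission
width is the smaller of the stored level sd and the trace's own measured
noise, so decoding a clean reconstruction does not let the stay-prior
swallow genuine short events (this makes idealization idempotent on its
own reconstruction). Events shorter than the dead time (default 0.5 ms,
≈1.5× the 1 kHz filter rise time) are merged into the neighbor closest
in current; event mean currents are recomputed from raw samples.

## Closure and dwell statistics

Brief intra-burst closures are closed events shorter than the burst
cutoff (default 100 ms); optionally only closures flanked by the same
conducting level (Oi→C→Oi) are kept. Frequency is normalized per second
of total analysis time by default, switchable to per-open-time; the
per-open-time estimator is unbiased for the generating closure rate
because closures initiate only while the channel is open. Dwell means
use the shifted-exponential MLE (mean minus dead time) to undo
left-truncation bias; dwell comparisons use Welch's unequal-variance
t-test. i–V slopes are ordinary least squares of current on voltage,
reported in pS. The re-entry consistency check compares the C→Oi
destination distribution against the open-conditioned time-weighted
occupancies by chi-square, pooling cells with expectation below 1.

## Trajectory pore metrics

The frames dialect is a TSV of per-frame labeled particle coordinates
(nm) with a JSON sidecar (frame interval, box, label). Analysis
cylinders are axis-aligned with z: height 11 nm and radius 2.5 nm (K⁺)
or 1 nm (water oxygens), centered per frame on the geometric center of
the M181 group; the selectivity-filter cylinder spans the T143–Y146
backbone-oxygen centers with a 0.25 nm radius. Geometric (unweighted)
centers are used because the dialect carries no masses. Boundaries are
closed; +z is extracellular.

A conduction event is a completed outward passage: a per-ion state
machine marks an ion SF-occupying when it is inside the SF cylinder and
fires one event when the ion next crosses above the SF's upper z-bound;
falling below the lower bound resets it. Coordinates are assumed
unwrapped in z; a frame-to-frame jump larger than half the box height
raises a warning rather than silently miscounting. Occupancy histograms
bin in-pore z at 0.05 nm, and the pool count averages the per-frame
number of ions between the M308 center and the SF lower bound. Gate
diameters are per-frame minimum atom distances between opposing chains
(pairs A–C and B–D), histogrammed at 0.1 Å with the mode reported; raw
minimum distances are reported without subtracting atomic radii.

The synthetic trajectory generator places fixed marker particles (M181,
M308, M302, I177, SF oxygens on four chains) and evolves K⁺/water
walkers by Gaussian steps with optional axial drift, reflecting at the
pore wall and box ends. It is the oracle bed for the counting machinery:
permeation counts and minimum distances are checked against brute-force
per-frame scans on seeded random trajectories. Absolute microsecond-scale
conduction rates, K⁺ pool sizes and gate-diameter distributions of real
simulations are outside what these synthetic walks emulate — passing
tests certify the measurement machinery, not molecular realism.

## Synthetic data vs real records

The generators emulate: multi-level piecewise-constant currents with the
published amplitude ratios and occupancies, exponential dwells, brief
closures at the published rate and dwell, Gaussian noise shaped by the
3 kHz / 1 kHz acquisition chain, and pore-shaped random-walk
trajectories. They do not emulate baseline drift, 1/f and seal noise,
polyamine block, rundown, stacked multi-channel openings, or real MD
physics; results on real data additionally depend on those factors.

## Problem sizes and numerical choices

Recovery runs use 60 s traces for amplitude detection, 300 s for
occupancy recovery, 100 s for closure statistics, and 25 pooled sweeps
per voltage for i–V fits — sizes at which the statistical bands (±0.03
amplitude, ±0.02 occupancy, 2 SE rates) hold with margin. The EM is
deterministic given the histogram; ties in level merging resolve toward
the count-weighted mean, with the anchored zero level always surviving.
Degenerate inputs (empty traces, all-zero levels, single-voltage i–V,
gapped trajectories) raise informative errors rather than returning
silent zeros; statistics with no qualifying events report NaN, never 0.

## Known limitations

* Level discovery assumes a common (tied) noise width across levels;
  strongly level-dependent open-channel noise would bias weights.
* The dead-time correction assumes exponential dwells; non-exponential
  (multi-component) dwell mixtures are reported as-is by the MLE.
* The two-class protonation model shares a single conductance map keyed
  on total protonation count; unequal per-class conductance effects are
  not separately parameterized.
* Permeation counting requires z-unwrapped coordinates; wrapped inputs
  only warn.
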