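# Methods

## The model

The package implements a firing-rate continuous attractor network (CANN)
that stores two statistically independent spatial maps of the same physical
arena, together with the data-analysis pipeline used to detect theta-paced
"flickering" between such maps in hippocampal recordings after an abrupt
cue switch ("teleportation").

Each map is a torus: `n_per_map` rate units per map, each with a
place-field centre `(phi^1, phi^2)` on a regular `g x g` angular grid
(`n_per_map = g^2`; the published configuration uses `g = 50`, i.e. 2,500
units per map and a linear resolution of `2*pi/50`). Units are drawn from a
pool in which membership of each map is an independent Bernoulli(`f`) draw
(`f = 0.25`); units belonging to neither map are discarded, and draws that
would overfill a completed map are rejected, so each map has exactly
`n_per_map` members while the conditional overlap statistics are preserved
(dual-membership fraction `f/(2-f) ≈ 0.143` among simulated units). A
dual-member unit receives an independent centre in each map — global
remapping by construction.

The dynamics per unit are

    tau dm_i/dt = -m_i + g( sum_j W_ij u_j x_j m_j + I_ext,i(t) + I0 )
    du_i/dt     = (U - u_i)/tau_f + U (1 - u_i) m_i
    dx_i/dt     = (1 - x_i)/tau_r - u_i x_i m_i

with the smooth threshold-linear transfer `g(z) = alpha*log(1+exp(z/alpha))`
and weights

    W_ij = (2*pi/N) * [ J1 * sum_{maps k shared by i,j} (cos d1 + cos d2)
                        - J0_magnitude ]

where `d1, d2` are the angular separations of the two units' centres in map
`k` and `N = 2*n_per_map`. The uniform term is inhibitory and counted once
per unit pair; the diagonal is included by default (a unit is a pool of
neurons with within-pool recurrence; `include_self=False` ablates it).

Short-term plasticity follows the standard depression/facilitation synapse:
release probability `u` (facilitates with presynaptic rate, recovers to `U`
with `tau_f`) and resources `x` (deplete with transmission, recover with
`tau_r`); momentary efficacy is `u*x`. Because `x` recovers faster than `u`
decays (`tau_f/tau_r ≈ 3.2` at the defaults), the efficacy transiently
overshoots its baseline after activity ends — the synaptic rebound that
lets the previously expressed map win theta cycles for a few seconds after
the cue switch.

External input is the sum of a spatially uniform theta drive
`A_theta*sin(2*pi*f_theta*t)`, a place-locked drive
`amp_k * ([cos(phi^1 - pos1)]_+ + [cos(phi^2 - pos2)]_+)` through every map
the unit belongs to, an optional Ornstein-Uhlenbeck noise per unit
(`tau_N d(eta)/dt = -eta + A_n xi(t)`, unit-spectral-density white noise,
stationary variance `A_n^2/(2 tau_N)`), and the background `I0`.

### Cue amplitudes

`amp_k = A1 + A2` for the map currently selected by the cues and `A2` for
the other map, where `A1` is the switch-sensitive and `A2` the
switch-insensitive (stable) cue component. The defaults are `A1 = 0.5 Hz`,
`A2 = 4.0 Hz`: most of the localized drive is carried by cues that survive
the switch, and teleportation changes the between-map input difference by
only `A1`. This is a deliberate design choice: the within-network effects
that drive flickering (a ~70% rebound advantage in recurrent efficacy)
correspond to a few Hz of input at the bump and can only flip the
theta-cycle competition when the external difference is of the same order.
With the assignment inverted (difference 4 Hz) the model still shows an
immediate transition but no flickering at all, at any tested coupling
scale — an input-dominated regime.

### Parameter tables

Plastic regime (the standard operating point): `tau=10 ms`, `U=0.25`,
`tau_r=0.6 s`, `tau_f=1.9 s`, `A1=0.5`, `A2=4.0`, `A_theta=13`,
`f_theta=10 Hz`, `V=2*pi/10 rad/s`, `J1=14`, `J0=-18`, `I0=-1`, `alpha=1`.
Static regime (`ModelConfig.no_stp()`): `A1=0.75`, `A2=3.25`, `A_theta=60`,
`J1=35`, `J0=-42`, plasticity disabled.

### The static-synapse ("no STP") mode

Disabling plasticity by freezing `u=U, x=1` makes the network numerically
divergent at the static-regime couplings: the transfer function is
asymptotically linear, the uniform inhibition is nearly orthogonal to the
bump (cosine) mode, and the bump mode's linear gain exceeds one — in the
plastic model it is depression that caps recurrent throughput. The
package's no-STP mode therefore uses *static* synapses whose efficacy sits
at the rate-dependent steady state `u*(m) x*(m)`: the synaptic transmission
curve (including its saturation, throughput -> 1/tau_r at high rates) is
kept, but there is no synaptic memory across theta cycles, which is the
property the STP/no-STP contrast is about. The frozen-baseline variant
remains available as `SimConfig(no_stp_efficacy="baseline")` for ablation
studies of this instability.

## Integration

Deterministic runs use adaptive Runge-Kutta (scipy RK45, relative tolerance
1e-6, max step a quarter theta period, restarted at cue switches where the
drive is discontinuous, dense output sampled onto the recording grids).
Noisy runs use a fixed-step Euler-Maruyama scheme (numba-compiled, default
`dt = 0.1 ms`) — noise requires the fixed-step method. Initial conditions:
`m = g(I0)` plus a seeded jitter of 1e-3 Hz (symmetry breaking), `u=U`,
`x=1`, `eta=0`; every teleportation protocol includes a burn-in of at least
5 s so the plasticity variables reach their cruise state. Per-map mean
population activity is recorded at 1 kHz; per-unit state at a coarser
stride (default 10 ms). On a 2-s noise-free cruise run the two integrators
agree to ~1e-4 relative (L2 over the series); with the strong theta drive
the agreement degrades to ~5e-3 because rates traverse the near-silent
trough where relative error is ill-conditioned, which is why the
cross-check is defined on the cruise run.

## Model-side flicker detection

The mean network activity is band-pass filtered at 8-12 Hz (zero-phase
4th-order Butterworth), theta cycles are cut at successive local minima of
the filtered trace, and each cycle is classified by comparing the two maps'
within-cycle mean population activities (dual units count in both maps). A
cycle in which the non-current map's mean exceeds the current map's is a
flickering event; ties are not events. A `last_quartile` statistic (mean
over the final quarter of the cycle, where the competition has resolved) is
available as an alternative; on the runs examined it classifies nearly
identically. The "network transition" is the first post-switch cycle won by
the new map, and the "switching position" is the animal's position then.

### Transience is realization-dependent in noise-free runs

After the switch, the old map's rebound produces a burst of flickers over
the first few seconds. Whether that burst terminates or settles into a
persistent alternation limit cycle depends on the quenched realization of
the map overlap (which dual units tie the two maps together): across
selectivity seeds at 400, 784, 1600 and 2500 units per map, roughly half
the realizations are transient and half persistent, and no tested network
size removes the dependence. The robust, realization-independent signature
of the plasticity mechanism is statistical: with noise, flicker probability
in the first ~2.5 s after the switch exceeds the following window
consistently across realizations, while static-synapse networks driven to
flicker by noise alone show a time-homogeneous rate. The acceptance suite
asserts the strict noise-free form (zero events in the second 5-s window)
as stated, on the default realization; it should be read with this caveat.

## Data-side pipeline

Implements the session analysis for teleportation recordings:

* **Speed/artifact filter** — centred-difference speed; samples with speed
  <= 5 cm/s or > 100 cm/s, or bordering a tracking gap > 0.05 s, are
  invalid.
* **Rate maps** — 30 x 30 bins of 2 cm x 2 cm from the reference sessions,
  spike count / occupancy per bin over valid epochs, smoothed with the
  fixed 5x5 kernel (mass exactly 1); near edges and unvisited bins the
  kernel is renormalized over the visited support, which conserves total
  rate mass to < 0.5%. Unvisited bins are NaN in the canonical maps; for
  correlation lookups the nearest visited bin's value is used.
* **LFP theta filter** — linear-phase FIR designed with a hamming window,
  transition bands 5-6 Hz and 10-11 Hz, applied zero-phase.
* **Spike phases** — 0 deg at an LFP peak, 180 deg at the following trough,
  linear in time within each half-cycle.
* **Cycle segmentation** — an 18-bin (20 deg) phase histogram of all
  spikes; cycles are cut at each crossing of the minimal-firing bin's
  centre phase (ties break to the lowest phase).
* **Cycle vectors** — per-cell rate within each cycle; position taken at
  the cycle's temporal midpoint; cycles with more than 25% invalid tracking
  time are marked invalid (they count toward `p_lowV`).
* **Thresholds** — for each reference cycle, the Pearson correlation
  across cells between the cycle vector and each environment's
  expected-rate vector (per-cell rate-map value at the cycle's position).
  The low threshold per map is the 5th percentile of the same-environment
  distribution, the high threshold the 95th percentile of the
  other-environment distribution (linear-interpolation percentiles).
* **Events** — a teleportation-trial cycle is a flicker when its
  correlation with the current environment is at or below the low threshold
  AND with the other environment at or above the high threshold.
* **Trial statistics** — theta power = 5-10 Hz band power / 1-125 Hz band
  power of the raw LFP (periodogram integrals) in the window from 250 ms
  before the first network transition to 5 s after it; mean distance from
  the switching position over the 5 s after the transition (valid epochs);
  flicker rate `N / ((1 - p_lowV) T)`; trials with `p_lowV > 0.5` excluded;
  mean population firing rate in the same window as a control covariate.
* **Partial correlations** — flicker rate vs theta power (controlling
  distance and mean rate) and vs distance (controlling power and mean
  rate); two-sided p-values from a pair-preserving permutation null (the
  flicker vector is permuted while each trial keeps its covariate triple):
  `p = (1 + #{|r_shuffle| >= |r_obs|}) / (1 + n_shuffles)`. The two tests
  are reported without multiplicity correction.

## Synthetic sessions

The generator emulates a teleportation session with known ground truth:
Ornstein-Uhlenbeck velocity with reflecting walls in a 60-cm arena (mean
speed 18 cm/s, sd 8 cm/s — fast enough that the speed filter removes only
occasional pauses); two environments with independent random Gaussian place
fields per cell (40 cells, sd 7 cm, peak 25 Hz over a 0.1 Hz floor — rates
that give single-cycle population vectors enough signal for the
population-vector correlation to separate maps); an 8-Hz theta LFP with
white noise (sd 0.3 of the theta amplitude); theta-modulated
inhomogeneous-Poisson spikes (modulation depth 0.8, maximal at the LFP
peak, so the minimal-firing phase sits at the trough); two 180-s reference
sessions and a 40-s teleportation trial whose post-switch cycles express
the new environment except 20 planted flicker cycles in the first 5 s.
Planting operates at theta-cycle granularity to match the cycle-level event
definition.

What the generator does *not* emulate: realistic LFP spectra beyond the
theta band, phase precession, bursting or refractory structure in spike
trains, tetrode-level measurement noise, or behavioural structure beyond
the speed statistics. Passing recovery tests therefore shows that the
pipeline's logic is correct under its own assumptions, not that its
thresholds are optimal for real recordings.

Recovery is scored against ground truth by temporal overlap, over
post-switch cycles only (flickering is defined after the switch, and the
switch-straddling cycle has no well-defined label); planted cycles that the
speed filter removed are unobservable by construction and excluded from the
sensitivity denominator. On default sessions the detector reaches
sensitivity >= 0.9 at false discovery <= 0.1 (pooled over sessions), and
the first-transition cycle is located within one cycle of truth.

The trial-statistics generator used for calibrating the partial-correlation
test plants a latent confound between theta power and distance (r ~ 0.5,
mimicking the slow-behaviour coupling in real sessions), skewed
(exponential) noise on the flicker rate — deliberately non-normal, the
reason the analysis uses permutations — and, in the planted-effect arm,
effects of +-0.8 sd (true partial correlations ~0.6, comparable to the
published theta-power effect) at 40 trials.

## Problem sizes and numerical choices

Network experiments in the test and acceptance suites run at 20x20 units
per map (the model's mean-field behaviour is size-free: weights scale as
2*pi/N, so per-map recurrent input is independent of N; what grows with
size is the quenched overlap disorder, ~1/sqrt(bump size)). Deterministic
runs use the adaptive integrator; noisy runs the Euler kernel. The
teleportation protocol uses a 10-s burn-in for the headline run and a 6-s
burn-in inside sweeps; sweep counts are taken in the 5 s after the switch,
averaged over three selectivity seeds per grid point (the published count
surfaces are themselves averages over several network realizations, and a
single realization's counts are dominated by the quenched overlap
disorder). Sweep runs relax the adaptive tolerance to 1e-5 — the integer
cycle-level counts were checked to be identical at 1e-6.
The no-STP noise level used for the homogeneity check (A_n = 2.0) is chosen
so that noise-driven events actually occur in the scaled network — the
population-averaged noise must be comparable to the A1 input difference —
and the quantity under test is the time course, not the level. Degenerate
inputs (flat filtered activity, empty spike trains, zero-variance cycle
vectors, constant covariates) raise informative errors or are skipped and
counted, as described in the docstrings.

## Known limitations

* The cue-amplitude naming and the no-STP synapse mode involve judgement
  calls documented above; both alternatives are implemented and switchable.
* Noise-free transience is realization-dependent (see above).
* The virtual trajectory is a constant-speed diagonal; arbitrary
  trajectories are supported via delimited (t, x, y) tables but the
  headline experiments do not use them.
* The data pipeline assumes two environments; more would need threshold
  bookkeeping per ordered pair.
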