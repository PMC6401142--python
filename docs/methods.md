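# Methods

`neuralwaves` simulates large-scale brain dynamics as a network of
delay-coupled neural masses on a spatially embedded connectome and
quantifies the emergent metastable wave patterns.  This note records the
models, the analysis pipeline, the synthetic study conditions, and the
numerical choices, in enough detail to reproduce or criticize them.

## Node models

**Conductance neural mass.**  Each region carries three state variables:
the mean pyramidal membrane potential `V`, the inhibitory interneuron
potential `Z`, and the fraction of open potassium channels `W`.  The
pyramidal equation balances calcium (NMDA-modulated), sodium, potassium,
and leak currents, inhibitory feedback `-a_ie Z Q_Z(Z)`, and a nonspecific
input `a_ne I_0`; the inhibitory population is passively slaved to the
pyramidal firing rate at rate `b`; `W` relaxes toward its voltage-dependent
steady state at rate `phi`.  Channel activations and firing rates are
`0.5 [1 + tanh((x - T)/delta)]` sigmoids.  The model is nondimensionalized
with unit capacitance, so time is numerically in milliseconds.  Network
input enters the excitatory drive as a strength-normalized, delayed mixture
`(1 - c) Q_V(V_j) + c * sum_k C_jk Q_V(V_k(t - tau)) / sum_k C_jk`, where
`c` is the global coupling and `tau` a uniform conduction delay.

A note on the inhibitory sign: the inhibitory term appears in parts of the
literature with a `+` sign.  With `+` the model diverges for any sizable
perturbation; with `-` it reproduces the documented phenomenology (sustained
chaotic oscillation, coupling-induced synchronization), so `-a_ie Z Q_Z` is
used here.

Parameter defaults are the standard values for this model (conductances
`g_Ca = 1.1, g_Na = 6.7, g_K = 2.0, g_L = 0.5`; reversal potentials
`1, 0.53, -0.7, -0.5`; gate thresholds/widths as in the source model;
`r_NMDA = 0.25`, `I_0 = 0.3`, `b = 0.1`, `phi = 0.7`), except the
excitatory gain `a_ee = 0.8` and the firing-threshold spread `d_V = 0.68`.
Those two were calibrated, once, against three qualitative regime
constraints that the whole analysis rests on: (i) the uncoupled node is
weakly chaotic (Benettin largest Lyapunov exponent ~ +1e-3 / ms; verified
in the test suite); (ii) at `c = 0.6, tau = 1 ms` a network whose edges
have been fully randomized (weight multiset preserved) synchronizes
completely, while weak coupling (`c = 0.1`) leaves it incoherent; and
(iii) a spatially embedded exponential-kernel network at the same operating
point produces waves — high local synchrony with clearly submaximal global
synchrony.  The chaotic window in `d_V` is narrow (0.68 works; 0.66 or 0.70
yield periodic nodes whose networks synchronize globally and the waves
disappear), which is itself consistent with the mechanism: the metastable
wave regime lives on chaotic node dynamics.

**Wilson–Cowan network.**  Excitatory/inhibitory rate pairs
`du = -u + f(a_ee u - a_ie v - z_e + c u_network)`,
`tau_0 dv = -v + f(a_ei u - a_ii v - z_i)` with logistic `f`, delayed
strength-normalized excitatory coupling, and the standard parameter set
(`a_ee = a_ie = a_ei = 10, a_ii = -2, z_e = 1.5, z_i = 6, tau_0 = 1`,
`c = 5, tau = 2`).

**Kuramoto network.**  Phase oscillators `dtheta_j = omega_j +
c sum_k C_jk sin(theta_k - theta_j)` without delays and with `c = 0.0028`.
Natural frequencies follow the quadratic strength map
`omega_j = a - (a - b) ((s_j - s_a)/(s_b - s_a))^2` with `a = 0.1 Hz`,
`b = 0.01 Hz`, `s_a = min(s)`, `s_b = max(s)`: the strongest hub is the
slowest oscillator.  Frequencies in Hz are converted to angular rad/s and
the equation is integrated in seconds (default step 10 ms); this
interpretation (BOLD-scale time) is a documented choice.

## Integration

Fixed-step Heun (explicit trapezoidal predictor–corrector).  Delayed terms
are read from a ring buffer of committed states; the predictor stage reads
`t - tau` and the corrector stage `t + dt - tau`, both committed history for
`tau >= dt` (for `tau = 0` the network term is frozen at the step's start
in both stages).  This keeps the scheme second order, verified empirically
(error slope 2.0 on `dx = -x`) and against the method-of-steps series
solution of `dx = -x(t - 1)` (absolute error < 1e-4 at t = 5 with
dt = 0.01).  `tau` is rounded to an integer multiple of `dt` (logged).
Noise, when enabled, enters only the pyramidal equation as
`a_ne * sigma * sqrt(dt) * N(0,1)`, with the same increment in both stages
(stochastic Heun).  Initial conditions are uniform on a configurable
interval for `V` and `Z` (default ±0.2), `W` starts at its V-consistent
steady state, and all randomness flows from one seed, so `sigma = 0` runs
are bit-reproducible.  Numerical blow-up (`|V| > 20`) aborts with a
diagnostic; `W` leaving [0, 1] is flagged, not clamped.  The network
integrators are numba-compiled; a 512-node, 7 s run at dt = 0.01 ms takes
on the order of a minute on one core.

## Synthetic connectome

The generator emulates only what the wave phenomenology needs: bilateral
spatial embedding and an exponential weight–distance kernel.

* Geometry: two mirrored uniform slabs, 70 x 130 x 90 mm per hemisphere,
  separated by a 15 mm midline gap on each side (region centroids do not
  sit on the interhemispheric fissure).  Default 256 nodes per hemisphere
  (512 total, the scale of a fine whole-brain parcellation); mean 20 mm
  neighborhood occupancy ~ 10 nodes.  The gap is load-bearing: the callosal
  bottleneck it creates keeps global synchrony moderate while local
  synchrony stays high, which is what distinguishes waves from global
  locking.
* Weights: `w = base * 10^(slope * distance)` with default slope
  -0.021 log10 units/mm (weight falls 10x over ~48 mm, the order of
  empirical tractography kernels); optional symmetric lognormal jitter
  (default off — the reference network is a pure exponential kernel).
* Surrogates: `randomize_edges` reassigns a fraction of edge weights to
  random unused pairs (weight multiset preserved, degree sequence not —
  the "same weight distribution" surrogate); `geometric_surrogate`
  permutes weights within equal-count distance bins (weight–distance
  profile preserved); `threshold_network` implements density- and
  weight-based thresholding with optional binarization.
* Hub classification: strength `s_j = sum_k C_jk`; top/bottom `n_hubs`
  (default 75) by strength are hubs/non-hubs, the rest feeders; ties break
  by node index (stable sort).

What the generator does not emulate: cortical folding, heterogeneous
region sizes, distance-dependent delay distributions, interhemispheric
homotopic shortcuts, and the lognormal weight scatter around the distance
kernel.  Passing tests on this substrate show the machinery and the
qualitative regimes are right, not that quantitative details of any
empirical connectome are reproduced.

## Analysis pipeline

**Phases and synchrony.**  Per-node instantaneous phases come from the
analytic signal (Hilbert transform) of the mean-centered recorded variable,
with no additional filtering.  Order parameter `R_S = |mean_{j in S}
exp(i phi_j)|`; `R_global` is the time-mean over the whole network;
`R_local` averages, over nodes and time, the order parameter of each node's
20 mm neighborhood (self included).  Analysis sampling is 1 ms.

**Velocity fields.**  `v = -(|dphi/dt| / ||grad phi||^2) grad phi` on the
scattered node cloud.  The temporal derivative is the wrap-safe central
difference `angle(g(t+1) conj(g(t-1))) / 2dt` with `g = exp(i phi)`.  The
spatial gradient fits the pairwise wrapped increments
`angle(g_n conj(g_m))` of each node's neighbors (within 20 mm, else the 8
nearest) against their offsets by least squares — the discrete form of the
identity `dphi/dx = Re[-i e^{-i phi} dg/dx]`.  A per-node complex linear
fit of `g` itself was rejected: on a 60 mm-wavelength plane wave it
underestimates the gradient norm by ~27% (11% with distance weighting)
because `e^{i phi}` is curved over a 20 mm window, which would bias every
speed upward; the pairwise form is exact for linear phase whenever the
per-neighbor increment stays below pi (wavelengths above twice the
neighborhood radius).  Ill-conditioned neighborhoods (condition number
> 1e6 or < 4 neighbors) and gradients below 1e-6 rad/mm are masked.
Speeds in mm/ms equal m/s numerically.

**Transitions and dwell times.**  The network is split in two (hemispheres
by default; any axis partition is supported), each side's coherence series
is computed, and their sliding-window time-lagged Pearson cross-correlation
`C(t, l)` is formed (100 ms windows, 90% overlap, lags ±30 ms; lagged
samples spill over window edges rather than being zero-padded; sample
variance convention; windows with negligible variance relative to the
series scale are masked).  The detection statistic is `u(t) =
1 / Var_l[C(t, l)]`, thresholded at its temporal mean; each suprathreshold
interval contributes one transition at its `u` peak (earliest sample on
ties).  Dwell times are differences of consecutive transitions; no minimum
dwell is imposed.  Detection is validated against constructed sequences
with known gap centers and is robust to ±20% threshold perturbation.

**Flow scaffold.**  Each 1 ms velocity frame is treated independently.
From every node a forward and a backward (flow-inverted) streamline is
Euler-traced through an inverse-distance-weighted (power 2) interpolant of
the nodal vectors, using valid nodes within 20 mm of the current point; a
point with no valid node within 20 mm has left the cloud ("exited"), which
operationalizes leaving the brain for a point cloud without a mesh.  Steps
are capped at 8 mm (never upscaled), budget 200 steps, stagnation below
1e-6 mm terminates.  Streamlines shorter than 20 steps are discarded; the
last 5 points of the rest are clustered with DBSCAN (eps 6 mm, minPts 10);
forward-endpoint clusters are sinks, backward-endpoint clusters sources;
each cluster is assigned to the node nearest its centroid.  Visit counts
per node and their SD in non-overlapping 20 ms windows (averaged over
nodes) quantify scaffold variability; windows with and without transitions
are compared by two-sided Wilcoxon rank-sum.

**Recurrence and surrogates.**  Velocity-field recurrence is the mean over
valid nodes of the cosine similarity between a node's flow vectors at two
times (magnitudes ignored, keeping the matrix in [-1, 1]).  AAFT surrogates
rank-remap each channel onto a phase-randomized Gaussian copy; one shared
random phase sequence across channels preserves cross-spectra along with
each channel's exact amplitude distribution and power spectrum.  The
significance mask marks recurrence cells above the maximum (+1) or below
the minimum (-1) of the surrogate ensemble; under an exchangeable null the
expected marked fraction is `2/(n_surrogates + 1)`.

**Dwell-time tails.**  Five candidate families — Pareto `x^-alpha`,
exponentially truncated power law `x^-alpha e^(-x/lambda)`, lognormal,
exponential, Weibull — are fit by maximum likelihood with densities
renormalized on `[cutoff, inf)` (default cutoff 100 ms).  Pareto and
exponential have closed-form estimators; the rest use multi-start L-BFGS-B
(tolerance 1e-8); the truncated power law's normalizer is evaluated by
adaptive quadrature in a numerically stabilized form.  Vuong's statistic
`Z = sum(l_i) / (sqrt(n) sd(l_i))` on pointwise log-likelihood differences
compares non-nested fits.  Caveat: the truncated power law's two parameters
trade off strongly over a finite tail range, so single-sample MLEs at
n = 5000 carry ~5-7% sampling dispersion; consistency checks therefore
average the MLE over independent replicates.

**Functional connectivity.**  Raw FC is the Pearson matrix of the recorded
time series.  BOLD FC convolves each channel with a canonical double-gamma
HRF (peak 6 s, undershoot 16 s, ratio 1/6), then decimates to 0.1 s with a
zero-phase order-8 Chebyshev Type I antialiasing filter applied in stages,
optionally followed by global signal regression.  Amplitude-envelope
correlations band-pass to 8–13 Hz (order-4 zero-phase Butterworth), remove
zero-lag leakage per ordered pair by orthogonalizing one analytic signal
against the other, correlate 1 Hz bin-averaged Hilbert envelopes, and
average the two orthogonalization directions.

## Wave fixtures

Analytic phase fields with closed-form ground truth validate every
analysis stage without simulation: traveling plane waves, rotating waves,
and radial sources/sinks, all in the analytic-signal convention
`phi = omega t - k.x` so that the stored truth satisfies the velocity
formula exactly (asserted at construction, 1e-6 relative).  The metastable
sequence fixture concatenates plane-wave patterns with desynchronized
interludes and stores gap centers as ground-truth transitions.  To give
the sequence a detection-grade coherence signature, each segment's
wavenumber breathes (`gamma(t) k`, gamma oscillating with period 25 ms,
lagged 8 ms between hemispheres): each hemisphere's order parameter is then
a deterministic aperture function of the instantaneous wavenumber, so the
two coherence series oscillate in lagged lockstep — the striped lag
signature of a stable pattern.  During gaps the two hemispheres'
wavenumbers fluctuate independently with the same amplitude, destroying
lag structure without changing coherence levels (which would otherwise
create step artifacts in windowed correlations).  This construction was
chosen after stochastic per-node phase-jitter designs proved fragile: with
a few hundred nodes, realization noise in the order parameter (~1/sqrt(n))
swamps any stochastic modulation, whereas the wavenumber-breathing design
is deterministic given the node set.

## Reference study conditions

The headline synthetic experiment (module `neuralwaves.reference`) freezes:
512 nodes, the geometry and kernel defaults above, `c = 0.6`,
`tau = 1 ms`, `dt = 0.01 ms`, `sigma = 0`, 2 s transient discarded, 5 s
analysis window recorded at 1 ms.  At this operating point the wave state
coexists with a fully synchronized attractor: most initial conditions
produce waves, but a minority (~10–20%) collapse into global locking, and
within the wave state the global synchrony wanders over roughly 0.58–0.79
between initial conditions.  Synchrony summaries for the exponential
network are therefore reported as the median over a small ensemble of
initial conditions (`reference.wave_ensemble`, default 3 runs), which is
robust to occasional collapse; typical ensemble medians are `R_local ~
0.90–0.93` and `R_global ~ 0.60–0.70`, with tens of detected transitions
per 5 s whose dwell distribution is unimodal and strongly right-skewed.
The fully randomized surrogate synchronizes for every initial condition
tried (`R_local = R_global = 1.000`), so a single run suffices there.  The
5 s window and 512-node scale are the package's desk-scale choices.

## Known limitations

* Uniform delays only; distance-dependent or distributed delays are not
  implemented.
* The flow interpolant is inverse-distance weighting with a radius cap, a
  deliberate stand-in for mesh-based natural-neighbor schemes; streamlines
  within ~one interpolation radius of the cloud boundary are the least
  reliable.
* Hemisphere assignment is by sign of x (x = 0 goes left, logged); analyses
  requiring both hemispheres fail loudly on single-hemisphere clouds.
* The velocity estimator aliases for patterns whose phase advances more
  than pi per frame or per neighbor spacing; the 1 ms default frame rate is
  adequate for the neural-mass regime studied here (~15 Hz carrier) but
  fixtures at hundreds of Hz must be sampled faster.
* Cluster identity is not tracked across frames; source/sink dynamics are
  quantified through nodal visit statistics only.
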