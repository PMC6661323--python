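# Methods

## The model

`connectodelay` simulates whole-brain network models (BNMs): one
self-sustained oscillator per cortical region, coupled through a structural
connectome whose links carry a weight `w_ij` (streamline count) and a tract
length `L_ij` (mm).  Each link's propagation delay is `tau_ij = L_ij / v`
with conduction velocity `v = 5 m/s`.  Three local dynamics are provided,
all with natural angular frequency `omega0` (default 1 in model time):

* **Rössler** (chaotic): `x' = -omega0*y - z + eta + c`,
  `y' = omega0*x + a*y`, `z' = b + z*(x - c_par)` with
  `a = b = 0.2, c_par = 5.7`;
* **van der Pol** (nonlinearly damped):
  `x' = 2m(1 - beta*y^2)*x - omega0^2*y + eta + c`, `y' = x` with
  `m = 0.75`, `beta = 1`.  Note the restoring term acts on `y` (the
  standard Liénard form); a `-omega0^2 * x` variant, which has no restoring
  force and cannot oscillate, is available behind `literal_vdp=True` for
  inspection;
* **Landau–Stuart** (non-isochronous Hopf normal form), complex
  `X = x + i y`: `X' = X[(1 + i*omega0) - (1 + i*q)|X|^2] + eta + C` with
  `q = 0.5`.

The coupling is the linear difference
`c_i = (1/N) * sum_j K_ij [x_j(t - tau_ij) - x_i(t)]`, applied to the first
variable for Rössler and van der Pol and to both components (the complex
state) for Landau–Stuart; the additive Gaussian white noise `eta`
(`<eta_i(t) eta_j(t')> = 2 D delta(t-t') delta_ij`) enters the same
components.  `K_ij = K * w_ij` with the global coupling constant `K`.

### Units and time rescaling

Model time is dimensionless.  To simulate activity at a wall-clock frequency
`f`, time is rescaled so that the model's *principal oscillation* lands on
`f`.  The rescale factor is `c = 2*pi*f / omega_nat`, where `omega_nat` is
the measured cycle frequency of the uncoupled, noiseless oscillator — not
`omega0`: the Landau–Stuart cycle rotates at exactly `omega0 - q` (0.5 by
default), van der Pol at ~0.88 and Rössler at ~1.08 (`models.
natural_frequency`; Landau–Stuart closed-form, the other two measured once
per parameter set from a long uncoupled run).  Using the naive `2*pi*f`
factor would put the default Landau–Stuart model at `f/2` and destroy the
frequency dependence of the phase architecture that the whole analysis is
about.

Delays convert as `tau' = tau_seconds * c`, and the coupling constant and
noise intensity are interpreted as wall-clock rates (s^-1) and convert as
`K' = K / c`, `D' = D / c`.  This is the only convention under which the
reference parameter set — `K = 0.02`, `D = 0.25`, per-node effective
couplings `(1/N) sum_j K_ij` spanning ~0.19–7.92 — produces coherent
locking at all: treating `D = 0.25` as a dimensionless intensity swamps the
locking barrier by two orders of magnitude and no phase structure survives
(we verified this numerically).  All analytic-theory quantities are
evaluated in wall-clock units (`omega0 -> 2*pi*f`, `Omega` in rad/s, delays
in seconds, strengths in s^-1), which keeps the arcsin argument of the phase
prediction dimensionally consistent.

### Weight normalization

How raw streamline counts map onto `K_ij` is not standardised.  The default
is `normalization="none"`: weights keep their raw count scale and the
printed global coupling `K = 0.02` together with the `1/N` prefactor puts
the per-node effective coupling `(1/N) sum_j K_ij` on the 0.19–7.92 s^-1
band that the analytic theory operates on.  `"mean-nonzero"` and `"max"`
modes are available for connectomes distributed pre-normalised.

## Numerics

* **Integrator**: fixed-step Euler–Maruyama.  A fixed step is required by
  the ring-buffer delay history; correctness is verified by step-halving
  (the steady synchrony level changes by <0.2% under halving in the
  noiseless default configuration — the convergence check is run without
  noise because halving the step also changes the Wiener-path realisation).
* **Step size**: automatic `dt = min(2*pi/(256*omega0), min_delay/4)`;
  for Rössler `2*pi/1600` instead, because a step that resolves only the
  cycle collapses the chaotic attractor onto a periodic orbit (we check the
  largest Lyapunov exponent stays positive, ~0.05 at `dt = 0.004` against
  the ~0.07 reference).  Preconditions (≥200 steps per period, `dt` at most
  a quarter of the smallest delay) are enforced.
* **Delays** are rounded to the nearest step multiple (no interpolation);
  the `min_delay/4` precondition bounds the rounding error.
* **Initial history**: each node starts on its uncoupled attractor at a
  seeded uniformly random phase (Landau–Stuart exactly on the unit circle;
  the other models settled by integrating the uncoupled flow), and the delay
  buffer is filled by running the uncoupled deterministic dynamics forward —
  this avoids amplitude shocks at t = 0.
* **Noise** increments have standard deviation `sqrt(2*D*dt)` and are drawn
  chunk-wise by a seeded numpy Generator, so the compiled (numba) and
  reference (numpy) integration paths consume the identical stream and agree
  to ~1e-13; runs are bit-reproducible given the seed.
* Known Euler artefact: the Landau–Stuart radius equilibrates at
  `1 + dt*(omega0-q)^2/4`, linear in `dt` (the rotation inflates the modulus
  each step).  Irrelevant at production steps; amplitude-precision checks
  use a small `dt`.
* The default 20% of each run is discarded as transient.  Default steady
  durations are 60 s wall-clock at/below 10 Hz and 30 s above (several
  hundred cycles; enough for ≥40 PLV windows).

## Phase analysis

Protophases are the unwrapped `atan2(y - <y>, x - <x>)` angles (the printed
`arcsin(y/x)` form is not a monotone angle variable — unbounded ratio,
quadrant-blind — so the quadrant-correct angle is used; centring matters for
the Rössler cycle, which is not centred at the origin).  The
protophase-to-phase transformation bins the protophase mod 2*pi (64 bins),
averages the reciprocal angular velocity per bin, and integrates the binned
profile into a monotone, 2*pi-periodic map; the resulting series is rescaled
so its total growth equals the protophase's, making the mean frequency
preserved exactly.  Retrograde samples (possible for chaotic cycles) are
floored at a small positive bin weight to keep the map monotone.

Hemispheric Kuramoto order parameters `r e^{i Psi}` are complex means of
unit phasors; the entrainment frequency `Omega` is the least-squares slope
of the unwrapped `Psi(t)`, averaged over the two hemispheres (the pooled
order parameter nearly cancels in the anti-phase regime, so its argument is
noise-dominated there; per-hemisphere and pooled slopes are also reported).

A node is *synchronized* when its net rotating-frame drift
`|theta_i(T) - Omega*T - theta_i(0)|` is below one full turn over the steady
segment and the circular variance of `theta_i - Psi` (own hemisphere) is
below 0.5.  Net drift is used rather than total excursion because at the
operating noise level locked nodes occasionally slip by 2*pi and relock;
a steady frequency offset, or a single unbalanced slip, still disqualifies
a node.  Both thresholds are configuration knobs.

## Coherence statistics

Complex phase-locking values `cPLV_ij = <e^{i(theta_i - theta_j)}>` are
computed in sliding windows of 5 periods of the measured `Omega` with 25%
overlap, on a grid decimated to ~16 samples per period.  Significance is
per link: 100 surrogates permute the time samples of one series of the pair
(destroying all temporal structure), the maximum PLV across windows is
recorded per surrogate, and the threshold is the 95th percentile of the
maxima; a link is significant when its PLV exceeds the threshold in at
least 5 windows.  Permutations are shared across links within a surrogate,
which allows the whole null ensemble to be computed as windowed matrix
products; each link still receives a valid 100-sample null.  This
permutation null is deliberately weak (it ignores autocorrelation), and on
coupled runs essentially every link passes — consistent with the method's
known low bar for significance; the lag *architecture*, not the detection
rate, is the scientific output.

Per link we report the mean PLV over windows, the circular mean of the
window lag angles, and the angular deviation `sqrt(2(1-R))` (displayed as
`1 - deviation`); lag distributions are split into intra- (internal) and
inter-hemispheric (external) links.

## Analytic theory

For a two-cluster network with bimodal delays (weighted means `tau_int`
within and `tau_ext` between hemispheres, `dtau = (tau_ext - tau_int)/2`,
`ttau = (tau_ext + tau_int)/2`), the stationary phase of a locked node
relative to its hemisphere's mean field is

    <theta_i> = arcsin((omega0 - Omega) / (K_i r cos(Omega dtau))) - Omega ttau

and a node can lock only when `|omega0 - Omega| <= K_i r cos(Omega dtau)`.
Anti-phase locking between the hemispheres is selected when
`Omega * tau_ext` lies in the left complex half-plane
(`cos(Omega tau_ext) < 0`): at 5 Hz `Omega*tau_ext ~ 0.6 rad` (in-phase),
at 20 Hz `~2.4 rad` (anti-phase).  `K_i` is the node's effective coupling
`(1/N) sum_j K_ij` — the rate the phase reduction of the `1/N`-coupled model
actually produces.  `r` and `Omega` are taken from the simulation (each node
uses its own hemisphere's time-averaged `r`); a self-consistent fixed-point
solve is possible future work.  Agreement is quantified as the circular RMSE
after an optimal common rotation (the prediction is defined up to the
mean-field phase origin) plus a Spearman rank correlation, over nodes that
are synchronized in simulation and have a defined prediction.

## Synthetic connectomes

The generator emulates the statistics the analysis relies on, not any
specific subject: two hemispheres of 34 regions; link existence
`p_ij = min(1, density * b_i * b_j)` with per-node log-normal propensities
`b_i` (sd 0.8) and densities 0.6 intra / 0.25 inter; log-normal weights
(log-sd 1.0, log-mean 5.82) with inter-hemispheric weights halved
(tractography under-represents inter-hemispheric tracts); gamma link delays
(CV 0.3) with class means rescaled deterministically so the
coupling-weighted means are exactly 6.5 ms (intra) and 19.6 ms (inter) at
5 m/s, from which tract lengths follow.  The degree heterogeneity is what
spreads node strengths over more than an order of magnitude — as in real
connectomes — while keeping each node's input field an average over many
links, i.e. close to the hemispheric mean field assumed by the theory; the
defaults put the effective-coupling band at ~0.19–8 s^-1 (ensemble medians
within a factor ~2 of the reference 0.19/2.93/7.92).  Weights and lengths
are drawn independently (no weight–length correlation), homotopic links get
no special treatment, and nodes have no 3-D embedding; real connectomes
differ in these respects, so passing tests demonstrate the phase-architecture
mechanisms, not subject-level prediction.

## What the experiments show

With the defaults (`K = 0.02 s^-1`, `D = 0.25 s^-1`) the simulated phase
architecture reproduces the expected delay-driven organisation: at 5 Hz both
link classes lock near zero lag; at 20 Hz intra-hemispheric links stay
zero-lagged while inter-hemispheric links lock near ±pi; stronger nodes lag
the weaker within each hemisphere (negative strength–phase rank correlation
among locked nodes, all three models); the entrainment frequency sits
slightly below nominal; and for the limit-cycle models the locked-phase
pattern matches the analytic prediction to <0.3 rad circular RMSE at 5 Hz.
Amplitude falls with node strength at 20 Hz for the two limit-cycle models;
for the chaotic Rössler model our runs show the opposite sign (coupling
regularises the chaotic attractor toward a larger, more harmonic cycle), so
the amplitude-suppression property should be read as a limit-cycle result in
this implementation.

Problem sizes used in the shipped checks: full-size runs are 68 nodes with
30–60 s of steady wall-clock activity; the multi-seed sign checks use
34-node connectomes with 15–30 s steady segments, five seeds per condition.
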