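# Methods

`schoolsim` simulates two-dimensional fish schools as self-propelled
particles, infers effective social forces back from trajectories with
binned force maps, and quantifies speed-based leadership from
time-delayed velocity statistics. This note records the model, the
conventions and numerical choices behind the implementation, and what
the synthetic tests do and do not establish about real data.

## The model

Each of N individuals (unit mass, so forces are accelerations in
cm/s²) obeys

    dv_i/dt = F_att-rep + F_align + F_fric-prop + F_noise

with the terms:

* **Attraction–repulsion** (pairwise): F_ij = −k (d_ij − d0) (x_i − x_j)/d_ij,
  a spring toward the equilibrium distance d0, with stiffness k = k_rep
  for d_ij ≤ d0 and k = k_att for d_ij > d0. The boundary is assigned to
  the repulsive branch; the force is zero there, so the choice only
  fixes determinism.
* **Alignment** (pairwise): F_ij = −μ (v_i − v_j), a restoring force on
  the full velocity vector (heading *and* speed).
* **Friction–propulsion**: F_i = −((|v_i| − v0)/τ_v) v̂_i, relaxing the
  speed to the preferred speed v0 on timescale τ_v without turning the
  fish. Setting τ_v = ∞ switches the term off cleanly.
* **Noise**: σ_v ξ_v v̂_i + σ_φ ξ_φ φ̂_i with independent unit Gaussian
  white noise along and perpendicular to the heading; amplitudes carry
  units cm/s^(3/2), consistent with the √dt Euler–Maruyama scaling.

Social partners are **Voronoi neighbors** (Delaunay-adjacent
individuals, a standard proxy for visual interaction networks).
Pairwise social forces are combined as a weighted **mean** with weights
proportional to 1/d_ij, normalized to sum to one per individual. The
unnormalized weighted-sum reading is preserved behind
`normalize_weights=False`; in side-by-side runs it destabilizes speeds
(mean 13.5 ± 5.2 cm/s instead of ≈ 11 ± 3.3) and degrades both school
order and the inferred maps, so the normalized mean is the default.

Default parameters (the calibrated N = 39 black neon tetra school):
k_rep = 12.5 s⁻², k_att = 5 s⁻², d0 = 5.8 cm, μ = 1.5 s⁻¹,
v0 = 11 cm/s, τ_v = 1.6 s, σ_v = 6.4 and σ_φ = 2.6 cm/s^(3/2),
dt = 0.02 s.

### Variants

* **selective** — a fish interacts only with Voronoi neighbors moving
  *strictly* faster than itself (speed ties count as not-faster; they
  have measure zero). Weights are renormalized over the faster subset;
  a fish with no faster neighbor feels no social force. A consequence
  worth knowing: because slow fish are pulled toward fast ones but
  never the reverse, the stationary mean speed sits well above v0
  (≈ 19.4 cm/s at the default parameters) and the speed distribution
  broadens — the model trades speed realism for the attention
  mechanism.
* **explicit_antialignment** — the pairwise alignment term is replaced
  by a lookup of a tabulated 2D force field evaluated at the
  focal-frame relative velocity with the nearest neighbor
  (attraction–repulsion unchanged). Driving it with a field that is
  outward for slower neighbors destabilizes speeds (fast fish
  accelerate further), which is the phenomenon the variant exists to
  demonstrate.
* **persistent_random** — with probability rate r·dt per step a fish
  switches off its social forces and feels amplitude A in a fixed
  uniformly random direction for τ_p seconds. No canonical parameter
  values exist; they are required configuration.
* **nearest_only** — interaction restricted to the nearest neighbor; a
  testing aid.

### Integration

Semi-implicit Euler–Maruyama: forces are evaluated at the current
state, the velocity is updated first (deterministic force × dt plus
noise × √dt), and the position is advanced with the *new* velocity.
The Voronoi graph is rebuilt every step; the selective faster-than test
uses pre-update speeds. Recorded accelerations are the realized
velocity increment divided by dt — what an observer differentiating
the saved trajectory would measure. Headings are taken from the
current velocity; speeds below 10⁻⁹ cm/s raise a degenerate-state
error rather than guessing a heading (unreachable in practice at the
default parameters). Initial conditions: positions uniform in a disc
whose radius makes the expected nearest-neighbor distance ≈ d0, speeds
v0, headings uniform; the first 1,000 frames are discarded as
transient in production runs.

## Force maps

A force map approximates an effective force term as the binned mean of
individual accelerations against one relative variable, everything
else averaging out. Coordinates and responses are expressed in the
focal frame (y along the focal heading, x to its right), with
focal-minus-neighbor sign conventions: x_i − x_NN for the
attraction–repulsion map and v_i − v_NN for the alignment map. Default
grids: ±20 cm and ±15 cm/s, 30 × 30 bins, bins with fewer than 50
samples masked. Neither bin geometry nor the count threshold has a
canonical published value; both are configuration.

The radial projection (mean vector dotted with the outward unit vector
of each bin) separates attraction/alignment (inward, negative) from
repulsion/antialignment (outward, positive). The equilibrium distance
is recovered as the sign change of the angularly averaged, count-
weighted radial profile of the relative-position map; the estimator
uses a finer 0.5 cm grid so the crossing interpolation error stays
well below the ±0.5 cm acceptance band (recovered 5.66–5.72 cm for a
generating d0 of 5.8 cm at 31k–151k frames).

Conditional filters (nearest-neighbor distance, wall distance given a
tank geometry, approaching/receding via the sign of
(x_i−x_NN)·(v_i−v_NN), relative heading angle, focal speed,
faster/slower neighbor, group size) compose conjunctively and exist
mainly for experimental-data robustness checks; simulations are
unbounded, so the wall filter takes explicit tank geometry.

For the explicit-antialignment driving field, masked bins are filled
from the nearest valid bin *before* Gaussian smoothing (σ = 2 bins) so
the kernel never mixes mask sentinels; interpolation is bilinear with
boundary clamping outside the grid.

## Which kinematics feed which analysis

Simulated ensembles carry integrator kinematics; tracked data carry
Gaussian-derivative kinematics (below). The package applies them
deliberately:

* **Standard-model map closure** (zero crossing at d0; alignment map
  inward everywhere) uses the integrator's own kinematics — the
  model's ground truth. Smoothing is avoidable here and in fact
  introduces mild systematic outward artifacts at mid radii.
* **Selective-signature and leadership analyses** first pass simulated
  positions through `reprocess_like_experiment` (the same σ = 2
  Gaussian-derivative pipeline applied to tracked fish). This is not
  cosmetic. The apparent antialignment of the selective model and the
  self-delay duality are signatures of *sustained* velocity
  differences; with raw per-step kinematics the conditioning variable
  is dominated by instantaneous noise and the signatures wash out
  (16% of upper-half bins outward instead of ~75%; no outward surrogate
  map at negative delay). For an Ornstein–Uhlenbeck velocity the
  equal-time correlation between acceleration and velocity is −σ²/2,
  which cancels the mean-reversion asymmetry in raw data; smoothing
  sets that equal-time term to zero, leaving the asymmetry that
  distinguishes leaders from followers.

## Observables

Polarization |⟨v̂_i⟩|; mean nearest-neighbor distance; convex-hull area
per individual (degenerate collinear sets return 0 with a warning);
Voronoi contact durations as maximal runs of consecutive adjacency
(strict contiguity by default — a one-frame gap ends the episode; a
gap tolerance is configuration); signed turning rate
ω = (v × a)/|v|², chosen over finite-differencing heading angles to
avoid 2π-wrap artifacts; binned PDFs with a Bernoulli error band
√(p(1−p)/n)/binwidth using the total sample count n.

Matched standard vs selective runs reproduce the documented ordering:
the selective school is less polarized, with larger variance of
nearest-neighbor distance and of speeds, larger hull area per capita,
and stochastically shorter Voronoi contacts.

## Leadership

The surrogate self-delay construction pairs a fish at time t with
itself at t + τ (τ a multiple of dt, default 0.2 s; no interpolation).
Positive τ makes the present fish a follower by construction and its
alignment map inward everywhere; negative τ makes it a leader and the
map outward — both at 100% of populated bins on smoothed standard-model
runs.

Delayed correlations pool all (fish, frame) samples: the mean heading
dot product v̂_i(t)·v̂_NN(t+τ) and the Pearson correlation of speeds,
per signed delay. The nearest neighbor is fixed at the reference time
and followed by identity to t + τ; edge frames are dropped, not
wrapped. State filters (faster/slower than the neighbor, frontal/rear
along the focal heading) are evaluated at the reference time. On
selective-model runs the faster-filtered orientation curve peaks at
τ ≈ +0.2 s and the slower-filtered at τ ≈ −0.15 s — faster fish lead —
while frontal/rear curves stay near the all-samples baseline. The
faster and slower curves need not mirror each other: nearest-neighbor
relations are non-reciprocal, so no symmetry is asserted.

## Preprocessing of tracked data

Occlusion gaps up to a configurable length (default 10 frames) are
filled coordinate-wise with cubic splines; longer and boundary gaps
stay masked. Image coordinates are warped onto the physical tank plane
by the homography mapping the four imaged corners to a square of the
physical side length. Positions are then smoothed with a Gaussian
kernel (σ = 2 frames, truncated at 5σ, reflect-padded boundaries with
the first/last 5σ frames flagged), and velocities/accelerations come
from first- and second-order Gaussian-derivative kernels divided by dt
and dt². The sampled derivative kernels are moment-corrected so the
first-order kernel exactly differentiates linear sequences and the
second-order kernel exactly recovers the curvature of quadratics —
the raw sampled kernels carry an O(10⁻³) relative bias at σ = 2 that
the correction removes.

## Parameter recovery and numerical conventions

The closed-form acceptance estimates recover generating constants from
simulation output: terminal speed of a noiseless individual (→ v0),
speed-relaxation and pair-alignment decay fits (→ τ_v and μ), and
linear regression of the pairwise force magnitude on |d − d0| over
five distances per branch (→ k_rep, k_att, exact to rounding). The
exponential fits invert the integrator's one-step multiplier,
λ = (1 − e^{slope·dt})/dt, rather than reading the continuous-time
slope directly: forward-Euler data decay by (1 − λ dt) per step, so
the naive fit would carry an O(λ dt) bias (≈ 3% for the pair-alignment
rate 2μ = 3 s⁻¹ at dt = 0.02 s) that the inversion removes exactly.

Problem sizes: production-style analyses use N = 39 with 31,000 frames
(1,000 discarded), ≈ 1.17 million focal samples per map; full
151,000-frame runs reproduce the same statistics and were used to
confirm that the qualitative map signatures are not small-sample
effects.

## What the synthetic tests do and do not show

The generator *is* the model under study, so closure tests (simulate →
infer → recover the generating parameters and sign structures)
validate the inference machinery and the internal consistency of the
selective-attention explanation. They do not validate the model
against real fish: burst-and-coast locomotion, wall interactions,
body shape, and 3D motion are all absent (the simulation space is
unbounded, so large turning rates are rarer than in a tank), and the
selective variant's elevated mean speed is a known idealization.
Inferences from force maps are not unique — different interaction
rules can produce similar maps — which is precisely why the surrogate
and delayed-correlation cross-checks exist.
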