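# Methods

## Model

`burstschool` simulates N identical fish on an unbounded plane. Time and
length are dimensionless: the mean kick duration and the mean kick length
are both 1 (so the cruising speed scale is 1), and an optional physical
scale `l0_metres = 0.07 m` is carried for reporting only.

Each fish alternates instantaneous **kicks** with straight **glides**.
During the glide that starts at the kick at time *t* with duration τ and
length l = τ, the position advances along the locked heading by
l·(1 − e^{−s/τ₀})/(1 − e^{−τ/τ₀}) after elapsed time s, i.e. the speed
decays exponentially with relaxation time τ₀ (default 0.8) from
(τ/τ₀)/(1 − e^{−τ/τ₀}) at kick onset, and the glide covers exactly the
kick length. At the kick the heading is updated by Gaussian noise of
standard deviation γ_R (default 0.2) plus the attraction–alignment
contributions of the k most influential neighbours (the neighbours that
would turn the focal fish the most, ranked by |δφᵢⱼ|, ties to the lower
id). Neighbour states are dead-reckoned to the focal kick instant: a
gliding neighbour's heading is its locked post-kick heading and its
position follows the glide profile. The event loop processes kicks in
time order (ties by ascending id); a kick changes only the kicking fish,
so the schedule is exact, not time-stepped.

The pairwise heading change is

δφᵢⱼ = γ_Att·d·sinψ/(1 + (d/l_Att)²) + γ_Ali·(1 + ε·cosψ)·e^{−(d/l_Ali)²}·sin(φⱼ − φᵢ),

odd in the perception angle ψ for attraction (neighbours to the left pull
left) and odd in the heading difference for alignment, with anisotropy ε
(default 0.8) making neighbours ahead more aligning than those behind.
There is no hard perception cutoff in the dynamics: both kernels decay on
their own ranges (defaults l_Att = l_Ali = 3). The critical distance
4·l_Att appears only in the group-detection analysis.

## Parameters and defaults

| parameter | meaning | default |
|---|---|---|
| γ_Att, γ_Ali | attraction / alignment strength | required (explored: 0–0.6 / 0–1.2) |
| l_Att, l_Ali | interaction ranges (kick lengths) | 3 |
| ε | alignment anisotropy | 0.8 |
| γ_R | heading-noise intensity | 0.2 |
| τ₀ | glide speed relaxation time | 0.8 |
| k | influential neighbours used | 1 (or 2) |
| N | group size | 100 |
| kick distribution | truncated Gaussian, mean 1 | s.d. 0.25 on [0.2, 2.0] |
| noise mean | mean of g | 0 |

Open choices and how they were fixed:

* **Kick distribution.** Only "bell-shaped with mean 1" is constrained.
  We use a Gaussian of mean 1 truncated to [0.2, 2.0] with s.d. 0.25
  (kicks typically half to one mean duration, rarely up to twice);
  both the s.d. and the truncation are configurable.
* **Noise mean.** A unit-mean noise term would add a constant turning
  bias γ_R per kick. We verified that such a bias destroys the reported
  phase structure (the milling point no longer mills, schooling
  polarization collapses), so the noise is zero-mean by default; a
  `noise_mean` parameter exposes the biased variant.
* **Initial disc radius.** The circle initialisation uses
  R = (l_Att/2)·√(N/π) so the typical inter-fish spacing √(πR²/N) equals
  half the attraction range.
* **First-kick phases.** Each fish's first kick event is drawn uniformly
  inside its first kick interval, so kicks desynchronise immediately; the
  first glide is simply interrupted at that instant. A synchronous start
  is available (`stagger=False`).
* **Run length.** "K kicks per fish" stops the event loop after N·K kick
  events (mean-per-fish semantics).

## Reproducibility and numerics

One master seed feeds a `SeedSequence` that splits into an
initial-condition stream and a 31-bit event-loop seed. The event loop has
two numerically identical backends: a readable pure-Python engine and a
numba kernel mirrored operation for operation (numba reproduces NumPy's
legacy `RandomState` sequences, which the Python engine uses); a test
asserts bit-identical trajectories. Social terms are evaluated through
exact trigonometric identities (cross/dot products with the focal heading
vector) rather than `atan2`; the angle-based form is kept as the public
`pair_interaction` and a test pins the two routes together at 1e-12.
Angles are radians wrapped to (−π, π]; all ties (event times, influence
ranks, nearest neighbours) resolve to the lowest fish id.

Degenerate cases: coincident fish get perception angle θ := 0 by
convention (the attraction term carries a factor d and vanishes anyway);
fish at the barycentre or with vanishing barycentre-frame velocity are
excluded from the milling average (M := 0 if all are).

## Observables and grouping

P(t) is the norm of the mean heading unit vector; for uncorrelated
headings E[P] ≈ √π/(2√N) ≈ 0.089 at N = 100. M(t) is the absolute mean of
sin(φ̄ᵢ − θ̄ᵢ) with positions and velocities taken relative to the
barycentre (velocities from the instantaneous glide speeds — headings
alone would leave the barycentre-frame direction undefined when speeds
differ). D(t) is the mean squared distance to the barycentre.

Groups are found by the chain-of-offspring recursion at critical distance
4·l_Att (a fish whose nearest neighbour is farther forms a singleton; the
chain stops when the current fish's nearest neighbour is already in the
group) followed by transitive merging of groups separated by less than
min(l_Att, l_Ali), measured as the minimum member-to-member distance.
The literal chain can close early — e.g. on equally spaced or coincident
configurations — leaving fragments that the merge step reconciles; a
single-linkage backend at the same critical distance is provided as an
alternative and the two agree on well-separated configurations (the
regime in which the statistic is interpreted). The within-group
dispersion DG is the unweighted mean over groups of the group-internal D,
singletons contributing 0.

Phase labels use run- and time-averaged values with the first half of
every run discarded as transient: dispersal if D > 200, bistable if
P ≥ 0.4 and M ≥ 0.3, else schooling (P ≥ 0.4), milling (M ≥ 0.3) or
swarming.

## Run budgets

Published batteries are large (phase maps: 20 runs × 2·10⁴ kicks per
pixel; long-run battery: 1000 runs × 4·10⁴ kicks). The package defaults
are desk-scale — sweeps at 5 runs × 2000 kicks per pixel, long-run
batteries at 50 runs × 4000 kicks — with the full budgets behind a
`--full-scale` flag. The test suite and the acceptance script use the
desk-scale budgets; the long-run ordering checks (swarming most cohesive,
milling least, k = 2 fragmenting more than k = 1) already discriminate at
that scale, primarily through the final dispersion and the k = 2
fragmentation fraction.

## What the model does and does not capture

The simulator reproduces, at the reference points (γ_Att, γ_Ali) =
(0.22, 0.6), (0.37, 0.2) and (0.6, 0.6) with k = 1: a schooling state
whose polarization stays above 0.8 for almost all steady-state time, a
milling state with mean M ≈ 0.75, a swarming state with both order
parameters low and dispersion ≈ 2, a compact within-group dispersion
DG ≈ 2.5–5 in cohesive states, and short-run transect statistics (mean P
peaking ≈ 0.73 at 200-kick budgets on the γ_Ali = 0.6 transect).

A known sensitivity: runs started from the random-heading disc can shed a
small aligned subgroup during the disordered transient (locally aligned
fish leave together before global order forms and, once beyond the
alignment range, are held only by the weak attraction tail). Because D is
a squared statistic, a single stray subgroup dominates the mean final
dispersion of a batch, so cohesion criteria of the form "mean final
D ≤ 200" are strict at weak attraction: under the desk-scale scan
(5 runs × 1000 kicks, γ_Ali ∈ {0.2, 0.4, 0.6}) the measured minimal
cohesive attraction is ≈ 0.3 for k = 1 and ≈ 0.2 for k = 2 — the k = 2 <
k = 1 ordering is robust, the absolute location of the boundary is not
comparable across statistics of different run lengths and batch sizes.
Runs started from the aligned ellipse (the long-run battery's initial
condition) show no such transient loss: the schooling point stays a
single group for thousands of kicks.

Not modelled: walls or tank geometry, short-range repulsion, higher
angular harmonics of the interactions, hydrodynamics, 3-D motion, or
heterogeneity between individuals.
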