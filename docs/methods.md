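# Methods

## The model

`stochflock` simulates a group of N self-propelled agents in an unbounded
two-dimensional plane. Agent i carries a position **x**_i, a speed s_i and a
unit heading **e**_i, and moves ballistically, d**x**_i/dt = s_i **e**_i,
except at discrete behavioural events. The distinguishing ingredient is
*stochastic choice of interaction neighbours*: an agent perceives its K
nearest neighbours by distance rank (a topological, not metric,
neighbourhood), restricted to a visual field of total angle `fov`, and
interacts with k of them drawn uniformly at random. k = 1 is the stochastic
pairwise rule (one random neighbour out of K); k = K is the deterministic
local-averaging (Vicsek/Boids-like) rule; K = k = 1 is
nearest-neighbour-only interaction.

Updating is asynchronous and event-driven. Events arrive as a Poisson
process with total rate Λ = N(r_p + r_c + r_s); each event picks a uniform
focal agent and a type with probability proportional to the rates — a
global Gillespie construction, equivalent to independent per-agent
exponential clocks. Exactly one agent interacts at any instant. The rules:

- **Alignment** (rate r_p): copy the heading and speed of the chosen
  neighbour (k = 1), or adopt the circular-mean heading and mean speed of
  the k chosen neighbours. An undefined circular mean (zero resultant)
  keeps the current heading.
- **Attraction** (rate r_c): head towards the centroid of the chosen
  neighbours with speed s0·d/ε clamped to [s_min, s_max], where d is the
  distance to the centroid — farther means faster. An agent exactly on the
  centroid keeps its heading and resets to the cruise speed s0.
- **Spontaneous turn** (rate r_s): redraw the heading from a wrapped normal
  centred on the current heading with variance σ_a², and the speed from a
  normal around s0 with variance σ_s², redrawn until inside
  [s_min, s_max].
- **Collision avoidance**: a continuous control, not a scheduled event.
  Between events the world advances in ballistic micro-steps of length
  min(0.01, ε/(10·s_max)); in each micro-step every agent with another
  agent closer than d_c rotates away from the nearest offender at
  `avoid_turn_rate` (never past facing directly away; coincident pairs
  rotate counter-clockwise) and has its speed multiplied by
  `avoid_slow_factor`, clamped below by s_min. Treating avoidance as part
  of how agents move (rather than as a rate process) follows from its role
  as a reflex; its cadence is tied to the micro-step, so the slowdown per
  unit time depends weakly on the micro-step length. Micro-steps are cut at
  snapshot times, which adds a handful of extra avoidance applications per
  run; at the default step this is negligible.

The **minimal variant** (`minimal=True`) reduces the agents to point
particles: full 2π perception, no collision avoidance, speed pinned at s0.

Initial conditions place the agents uniformly in a disc of radius ε·√N
(constant initial density regardless of N) with uniform headings and speed
s0. A single NumPy `Generator` seeded per replicate (`base_seed +
replicate`) drives every draw, so runs are bit-reproducible; replicates at
different K share seeds, making K-contrasts paired.

## Cohesion statistics

A *cluster* at a sample time is a connected component of the graph joining
agent pairs strictly closer than ε — chained density clustering (DBSCAN
with the core-point minimum reduced to 1). The *cohesion parameter* C is
the largest-cluster fraction averaged over post-burn-in sample times (and
over replicates in sweeps); C = 1 means the group never fragmented. Nc is
the mean cluster count. The first 20% of each run is discarded as burn-in.
Alternate measures (mean nearest-neighbour distance, convex-hull area,
mean distance to the barycenter) are provided as diagnostics.

## The attraction interaction network

Every attraction event defines directed edges focal → partner. Tiling the
post-burn-in span into disjoint windows of length t_w = ε/s0 (the time to
cross one cluster scale at cruise speed) gives a per-window binary
adjacency A; its transitive closure is the reachability matrix, and the
classes of *mutual* reachability (strongly connected components, with
every node reaching itself by convention) are the sub-groups. The network
parameter Np is the window-averaged largest-sub-group fraction. Only
attraction events enter A by default (cohesion is about attraction);
alignment edges can be included for exploration via `build_adjacency` on a
filtered log.

## Mean-field SDEs for the polarization order parameter

For the alignment dynamics in the mean-field limit the scalar order
parameter m ∈ [−1, 1] follows, under pairwise copying at rate c with
spontaneous turns at rate a,

    dm/dt = −a·m + sqrt((c(1 − m²) + a)/N)·η(t),

and with an additional higher-order (averaging-like) interaction at rate h,

    dm/dt = −a·m + h(1 − m²)m + sqrt(((c + h)(1 − m²) + a)/N)·η(t).

Pairwise copying has no deterministic ordering term: order is induced by
the multiplicative noise and fades as N grows (mean |m| ~ N^(−1/2)).
The higher-order drift has stable roots at ±sqrt(1 − a/h) for h > a, so
averaging holds order deterministically. Integration is Euler–Maruyama
with per-step clamping of m to [−1, 1] (reflecting schemes rejected for
simplicity); the default step is 10⁻³ and a warning fires when the step
approaches the fastest relaxation time. The multiplicative-noise factor is
isolated behind `noise_form`: the default is (1 − m²); the alternative
reading (1 − |m|)² is selectable, as the two differ only at O(m²) near the
disordered state where the distinction matters least.

## Default parameters and calibration

Time and length units are set by the cruise speed s0 = 1 and the cluster
scale ε. The defaults (all configurable) are:

| parameter | value | meaning |
|---|---|---|
| r_p | 1.0 | alignment rate (1/time) |
| r_c | 0.7 | attraction rate (1/time) |
| r_s | 0.5 | spontaneous-turn rate (1/time) |
| σ_a² | 0.6 | turn-angle variance (rad²) |
| σ_s² | 0.01 | speed variance ((length/time)²) |
| s0, s_min, s_max | 1.0, 0.1, 2.0 | cruise speed and clamp |
| fov | 285° | visual field (75° blind cone) |
| ε | 1.5 | cluster scale / attraction reference (length) |
| d_c | 0.2 | avoidance trigger distance |
| avoid_turn_rate | π | avoidance angular speed (rad/time) |
| avoid_slow_factor | 0.5 | per-micro-step slowdown |

The defaults were calibrated, at the reference condition N = 30 and
t_end = 200, to reproduce simultaneously the qualitative regime this model
family is known for; each value is pinned by a distinct mechanism:

- **σ_a² = 0.6.** A wanderer that leaves the group heading outward holds
  the group in its blind cone; only spontaneous turns can bring it back
  into view. The heading decorrelates by diffusion at rate r_s·σ_a², so
  with variances much below ~0.2 escape becomes effectively absorbing on
  the simulated horizon, members are lost one by one, and — counter to the
  intended regime — cohesion *decreases* at large K (wanderers are chased
  by more agents). At 0.6 (sd ≈ 44° per turn) stragglers re-orient within
  a few turns and C rises monotonically with K, saturating once the
  neighbourhood reaches roughly a quarter to a third of the group.
- **r_c = 0.7 and fov = 285°.** Under nearest-neighbour-only interaction
  (K = 1) the group must fragment into clusters of two or three. Fragment
  size grows steeply with the attraction rate (at r_c = 2 the median
  fragment holds ~8 agents: frequent attraction glues leader–follower
  trains together) and shrinks with the blind cone (the chased nearest
  neighbour often sits behind the focal agent, so a wider blind cone breaks
  trains). fov below ~280° however re-creates the absorbing-escape problem
  at large K. The pair (0.7, 285°) keeps the median K = 1 fragment at ≈ 3
  agents while preserving C ≈ 0.9 at K = N − 1.
- **ε = 1.5.** The analysis window t_w = ε/s0 then carries r_c·t_w ≈ 1.1
  attraction edges per agent, enough for the largest mutually-reachable
  sub-group to grow systematically with K, so the network parameter Np
  rank-tracks C across K.

**Known limitation.** With ~1.2 edges per agent per window the directed
interaction graph sits near the strong-connectivity percolation threshold,
so Np plateaus near 0.15 rather than approaching 1. Np ≈ 1 would need
~3–4 attraction events per agent per window, and that much attraction is
incompatible (in this implementation) with break-up into clusters of 2–3
at K = 1. The package therefore reproduces the *trend* of the
network–cohesion correspondence (Np rank-tracks C across K, Spearman ρ
above 0.8 under the test conditions), not the absolute Np level.

## Study sizes

Sweeps default to N = 30, K ∈ {1, 2, 5, 8, 10, 15, 29}, 10 replicates,
t_end = 200 with snapshots every 0.5 — a desk-scale design whose
replicate-mean C curve has standard errors of a few hundredths, sufficient
to locate the saturation ratio to ±0.05. The network–cohesion rank
correlation compares replicate means at K values that partly sit on the C
and Np plateaus, where rank order is noise-limited, so the test suite runs
that one comparison on 16 replicates while keeping the 10-replicate design
for the threshold and break-up measurements. The SDE checks use horizons
of 10²–3·10³ with steps of 5·10⁻³–10⁻² where the Ornstein–Uhlenbeck
comparison needs long stationary stretches.

## What the synthetic fixtures do and do not show

Deterministic fixtures (lines, blobs, rings, hand-built event logs with
known cycle/half-cycle structure) give every analysis stage a known ground
truth: the cluster partition, the reachability matrix, the sub-group
partition and Np are all checkable exactly, independent of the simulator.
They validate the analysis code, not the model: passing them says nothing
about real animal groups. The simulation-based checks validate the model's
internal consistency (scheduler statistics, conservation of the speed
clamp, determinism) and its qualitative agreement with the collective
phenomena described above — break-up at K = 1, saturation of cohesion at
a fraction of the group size around a quarter to a third, averaging
needing fewer neighbours than pairwise — under the calibrated defaults. Real fish schools or bat groups differ in ways the model ignores
(3-D motion, body size and occlusion, heterogeneous individuals,
predation context), so agreement here is evidence about the mechanism, not
a fit to data.

## Numerical choices

- Angles wrap to (−π, π] with odd multiples of π mapping to +π.
- Distance ties in the topological ranking break by ascending agent id;
  coincident agents are mutually visible at distance 0.
- The zero-resultant circular mean returns NaN; the simulator's fallback
  is to keep the current heading.
- Cluster membership uses strict inequality (< ε); a pair exactly ε apart
  is disconnected.
- The truncated-normal speed draw resamples (up to 1000 times) rather than
  clipping, so the stationary speed distribution has no atoms at the
  bounds.
- CSV round trips write floats with 17 significant digits (exact binary
  round trip).
- `estimate_saturation_threshold` operationalizes "saturates" as the
  smallest K/N whose replicate-mean C reaches 95% of the value at
  K = N − 1, linearly interpolated between sampled K; the factor is
  configurable.
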