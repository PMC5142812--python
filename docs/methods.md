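# Methods

## The routing model

The terrain is discretized into a graph whose edge length corresponds to the
persistence length of the collective motion (~10 cm), so one hop is one
"decision" of the carrying team. Environments are lines of N nodes (source at
the left end, target at the right) or √N × √N four-neighbor grids without
wraparound, target at (⌊side/2⌋, ⌊side/2⌋) — "next to the center"; any
center-adjacent choice is equivalent by symmetry, so one is fixed.

Each non-target node carries one frozen advice pointer. With probability *p*
(advice reliability) the pointer is the node's *tree-parent*: the neighbor on
a shortest path to the target, with grid ties broken deterministically (step
along the axis with the larger absolute coordinate distance, row axis on
exact ties). This tie-break makes the correct pointers a spanning tree rooted
at the target, so pure advice-following in a fully reliable environment
reaches the target in exactly shortest-path hops. With probability 1 − p the
pointer is wrong, under one of two models:

- `uniform_neighbor` (default): uniform over the node's neighbors, *including*
  the correct one — the literal reading of the sampling description — so the
  realized accuracy is p + (1 − p)·E[1/deg].
- `flip` (lines): the neighbor away from the target; the left-end node has a
  single neighbor, so its "flipped" advice is necessarily correct. This model
  produces the all-advice-wrong worst case.

The **Probabilistic-Following** agent is memoryless and orientation-free: at
each node it moves to the advised neighbor with probability *q* and to a
uniformly random neighbor otherwise (the random step may coincide with the
advice; the effective follow probability at degree d is q + (1 − q)/d). Walks
are censored at a step cap (default 10⁶) and censored runs are returned
flagged, never dropped; downstream metrics decide their treatment.

**Exact oracle.** On graphs up to 10⁴ nodes the expected first-passage time is
computed by solving (I − Q)t = 1 over the transient states of the PF kernel
(sparse LU). At q = 1 the kernel's support is only the advice edges; nodes
from which the target is unreachable (advice cycles) get an infinite expected
time, determined by reverse reachability before solving. Monte-Carlo batches
use a numba-compiled kernel with one RNG stream per walk derived from
(base seed, walk index), making batches reproducible and order-independent.

## Stretch and experiment protocols

Stretch of a run is hops divided by the shortest-path hop distance; a
censored run contributes its lower bound, cap/shortest. **Effective stretch**
is the mean of the lowest ⌈0.9·n⌉ values (the worst 10% discarded, with
⌈·⌉ because 0.9·n is rarely integral): the raw expectation can be unbounded
in adversarial settings, and the trim typically removes exactly the censored
runs. With trim 0 it reduces to the plain mean and it is non-increasing in
the trim fraction.

Line sweeps take the **median** first-passage time over independent advice
configurations, one walk per configuration; cells where more than half the
runs were censored are flagged. Grid scans pool walks over environments ×
uniformly drawn sources (source ≠ target). The robustness curve divides the
effective stretch of a fixed reference policy (q = 0.8) by the minimum over a
q scan in steps of 0.1 (the scan granularity is a package choice; finer grids
change the optimum location by less than the sampling noise).

Default repetition counts — line: 10⁴ configurations per cell; heatmap grid:
200 environments × 20 sources; robustness scan: 100 environments × 5 sources
per (p, q) cell — are chosen so the full suite runs on one CPU in minutes
while keeping cell standard errors a few percent; paper-scale counts (10⁶
line configurations, 1000 × 50 grid) are reachable through the same
interfaces. One consequence of the reduced scan: the per-p minimum over 11
noisy cells is slightly biased low, inflating robustness ratios by a few
percent.

At reliability 0.9 the fixed q = 0.8 policy is itself the scan optimum
(ratio 1); the ratio stays below 1.5 for reliabilities above 0.4 and crosses
that bound at p = 0.4 — the bound genuinely holds only *above* 0.4.

**Escape model.** The enclosed-obstacle geometry is a half-line whose advice
all points back at the origin (every mark leads to a blocked slit); the origin
reflects. Interior nodes step backward with probability q + (1 − q)/2, so the
mean time to first reach distance n grows exponentially with per-step base
(1 + q)/(1 − q) — 9 at q = 0.8 — and the worked value E[T(2)] = 20 hops
follows from the two-state solve. `escape_rate_mapping` exposes the kernel's
observable rates: against-advice turns once per step_length/((1 − q)/2) cm
(70 cm at q = 0.8, 7 cm steps) and the base above. Field reversal rates fold
in collective effects outside this kernel, so the mapping is presented with
its parameters rather than fitted to observations.

## Scent-mark information

Angles (degrees, counterclockwise positive, reduced into [−180, 180) with
+180 → −180) are binned into 36 left-closed 10° bins. The plug-in entropy
H = −Σ pᵢ log2 pᵢ (0·log 0 = 0) gives absolute information
I = log2(36) − H ∈ [0, log2 36] bits per mark, and load-gained information
I = H_before − H_after, a signed quantity. Reference directions: the
load-to-nest line at marking time, or the track secant over a 2 s window
before/after the mark — a secant, not a fitted tangent, because it is
estimator-free and config-visible; both conventions are explicit arguments.

**Bootstrap SD.** Each of 10 000 replicates perturbs every raw bin count to
qᵢ + βᵢ√qᵢ with βᵢ ~ U[−1, 1], clips at zero, renormalizes and recomputes the
entropy; the SD of the replicate entropies is the error of any information
value affine in that entropy (load information combines the two independent
histogram SDs in quadrature). The √qᵢ scaling ties the perturbation to
counting error; clipping at zero is needed because the perturbation can push
near-empty bins negative. The U[−1, 1] interval makes the perturbation a
symmetric random term (a one-point interval would be a deterministic shift,
contradicting its role as noise).

`precision_from_bits` converts a bit budget to angular accuracy, 360/2^bits
degrees, unrounded.

## Marking-event detection and bouts

Speed is computed by central finite differences (one-sided at the ends) on
optionally moving-average-smoothed positions (default 3 frames);
acceleration is the derivative of speed. A marking event is a local speed
minimum below 3.5 cm/s whose centered 0.25 s window contains deceleration
magnitude above 30 cm/s² before the minimum and acceleration above
30 cm/s² after it ("around the minimum" operationalized as the max on each
side within the window). Candidates within one window are merged keeping the
deepest minimum. The window is centered rather than trailing, and the second
human-verification stage used on field footage is out of scope: this detector
is the automatic screen, thresholds config-exposed.

Bouts group consecutive marks of one ant with inter-mark gaps ≤ 2 s (the gap
is a package default; no numeric definition exists upstream). Start distance
is load-to-first-mark; bout length is the maximum load-to-mark distance over
the bout, each at the mark's own time. The median CI uses the conservative
binomial order-statistic construction: ranks (l, n+1−l) with the largest l
satisfying F(l−1; n, ½) ≤ (1−conf)/2, guaranteeing coverage ≥ conf; when no
such pair exists (n ≤ 5 at 95%) the full range (x₍₁₎, x₍ₙ₎) is returned.

## Synthetic-data generator

The generator emulates the statistical structure of cooperative-transport
recordings; its defaults are study conditions, fixed once:

| parameter | default | rationale |
|---|---|---|
| persistence length | 10 cm | straight-line scale of load motion |
| load speed | 1.5 cm/s | typical transport speed scale |
| frame rate | 50 Hz | resolves 0.2 s dips with ~10 samples |
| mark rate | 1.4 marks/s | collective marking rate near the load |
| angular concentration κ | 3.6 | gives ≈1.4 bits/mark, the field scale |
| bout start distance | 3.1 ± 1.9 cm | marks commence near the load |
| bout length median | 9.5 cm | observed median |
| bout length log-SD | 2.06 | places 2.2% (≈16/735) of bouts ≥ 6 m |
| dip depth / width | 4.5 cm/s / 0.2 s | clears both detector thresholds from a 5 cm/s cruise |

Load tracks are constant-speed correlated walks with Gaussian heading
increments of variance 2·step/ℓ, giving directional autocorrelation
exp(−s/ℓ) in arc length; the persistence estimator fits the initial decay
(correlation ≥ 0.3) only, because single-track long-lag correlations sit on
a noise floor that flattens the fit. Marks are a homogeneous Poisson process
with von Mises directions about the nest axis; bout lengths are log-normal —
a stand-in family, since only summary statistics (median, extreme tail) are
known upstream. Speed profiles are straight-line cruises with additive
Gaussian noise (SD 0.1 cm/s, small enough that smooth segments never trip
the acceleration gate) plus triangular dips at known times.

What the generator does **not** emulate: carrier-force dynamics, pheromone
evaporation chemistry, multiple simultaneously tracked ants with occlusions
and tracking noise, or correlations between marking rate and load motion.
Detector recall ≥ 95% and estimator round-trips on this synthetic data
therefore validate the implementations, not field performance — the field
sensitivity (93%) and empirical bits-per-mark values require the original
recordings and are deliberately not claimed.

## Numerical choices and limitations

- Walk censoring cap 10⁶ steps by default; censored counts are reported in
  every summary. At q = 1 in unreliable environments nearly all runs are
  censored and the effective stretch is a lower bound — those cells are never
  the scan optimum, so robustness ratios are unaffected.
- The linear-solve oracle is capped at 10⁴ nodes (sparse LU memory); singular
  systems outside the q = 1 cycle case raise rather than return garbage.
- Exponential fits are linear least squares on log y; R² is reported on the
  fitted (log) scale. Quadratic-crossing checks fit log FPT against log
  end-to-end distance (N − 1), the variable the scaling law is stated in.
- Reproducibility: every stochastic operation takes an explicit seed;
  identical seeds give bit-identical tables. Seeds for sub-tasks derive from
  numpy `SeedSequence`, masked to 31 bits for the numba kernel.
- Tests exercise reduced problem sizes (e.g. escape simulation cross-checks
  at distances ≤ 6, where mean escape times stay ≤ 10⁵ hops); the exact
  oracle covers the regimes where simulation is infeasible by construction
  (mean times growing as 9^N).
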