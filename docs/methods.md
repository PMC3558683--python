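# Methods

## Growth model

A neuron is grown as a set of *fronts* (active tips) processed in FIFO
order of creation. Each front update either terminates the front, extends
it by one straight segment, or extends it and splits it into two daughters.
The dendrogram therefore emerges from a modified Galton–Watson process —
after a segment of length *L* the front bifurcates with probability
1 − exp(−p·L) — while the geometry is decided segment by segment from a
biased directional sample. Topology and geometry are generated *together*:
a daughter can die (radius, proximity, boundary) while its sibling grows
on, so the realized dendrogram is itself shaped by the spatial forces.

Every growth direction is the normalized sum of a Gaussian sample and
three homotypic bias vectors:

| bias | form | models |
| --- | --- | --- |
| inertial | k·d̂_prev | membrane/cytoskeletal stiffness (straight motion) |
| soma-tropic | k/max(d, d₀)^γ · û(soma→tip) | radial tropism, ± = away/toward the soma |
| self-avoidance | k·Σ_j û_j /max(d_j, d₀)^γ | distance-mediated repulsion between sister branches |

The Gaussian is drawn per component with Marsaglia's polar rejection
method (`s = σ v₁ √(−2 ln r²/r²)`, r² = v₁²+v₂², 0 < r² < 1; the v₂
component of each accepted pair is discarded so that each draw maps to one
rejection loop). Its z component is multiplied by the *flatness* factor:
0 pins growth exactly to the xy plane, 1 is isotropic 3-D. Because only
the direction of the displaced sample is kept, a force of strength k
biases growth relative to σ but never guarantees alignment.

### Numerical and procedural choices

- **Force–distance law.** strength / d^decay with a distance floor
  d₀ = 0.1 μm, the simplest law consistent with "decays with distance to
  this power"; the floor removes the contact singularity.
- **Self-avoidance reference point** is the segment midpoint; the front's
  own last segment and its parent are excluded from the sum (otherwise the
  tip repels itself and double-counts inertia). Distances are
  center-to-center for the bias; the *termination* proximity test is
  surface-to-surface (midpoint distance minus both radii) and additionally
  exempts segments within two edges of the tip, so a freshly created
  daughter is not killed by its sibling at the branch point.
- **Branching law.** "At least one event over length L" is realized as the
  Poisson form 1 − exp(−p·L); the binomial alternative 1 − (1−p)^L agrees
  to first order but is ill-defined for non-integer L. Isolated behind
  `should_branch`.
- **Bifurcations.** Inter-daughter angle uniform on `angle_limit`,
  daughters placed at ±θ/2 about the parent direction; the containing
  plane is uniformly random about the parent axis in 3-D and fixed to xy
  when flatness ≤ 0.5. Daughter radii sum to `ralls_ratio · r_parent`,
  split by `daughter_asymmetry` (0.5 = equal); which geometric side gets
  which radius is decided by one uniform draw.
- **Segment length.** L = base_segment_length · (start_radius/r)^front_extension;
  0 gives the constant-rate pure Galton–Watson regime, negative values
  shorten segments as radii taper (raising branching frequency per μm),
  positive lengthen them. No clipping is applied; termination bounds the
  excursion in practice.
- **Stems** are sampled one at a time on the soma sphere (radius fixed at
  5 μm — the configuration schema deliberately has no key for it), with an
  adaptive minimum pairwise angle starting at 2π/(n+1) and relaxed by 10%
  after 50 consecutive rejections, which guarantees termination.
- **Termination order.** Branch level: minimum radius, then proximity,
  then boundary — evaluated in exactly that priority. Neuron level: no
  active fronts, total fiber length, bifurcation count; caps are checked
  between front updates, so the length cap can overshoot by at most one
  segment. Soma-to-stem offsets are tree segments but do not count as
  fiber.
- **Determinism.** One counter-based generator (NumPy PCG64) per neuron,
  consumed in a fixed documented order (direction x/y/z, branch draw,
  then angle/azimuth/side on branching), makes `grow_neuron` a pure
  function of (config, seed); SWC output is byte-identical across runs.
  Floats are serialized with shortest-round-trip precision so a write/read
  cycle is exact.
- The proximity scan is a vectorized all-pairs pass over segment
  midpoints; at the arbor sizes the packaged configurations reach
  (≤ ~6·10³ segments) this stays well under a second per neuron, so no
  spatial index is used.

## Morphometrics

- **Contraction**: Euclidean over path distance from soma to each tip; 1
  iff collinear, 0 for a closed loop, undefined (error) for zero path
  length.
- **Hausdorff fractal dimension** per branch, from ⟨E⟩^D = t. The shipped
  estimator is a structure-function fit: for ~12 log-spaced window sizes τ
  (up to a quarter of the path) the Euclidean excursion |p(i+τ) − p(i)| is
  averaged over all window starts and D is the inverse slope of ln⟨E(τ)⟩
  against ln τ, clamped to [1, 3]. Averaging over windows is what keeps a
  *single-branch* estimate usable: a plain regression of one excursion
  trajectory has per-walk scatter of ±0.6 on 10⁴-step random walks,
  versus ±0.09 for the windowed fit, while both are exact (D = 1) on
  straight paths. A two-point variant ln t / ln E is provided for
  comparison; it carries a finite-size bias of order 1/ln E (≈ +0.17 on
  10⁴-step walks). D is computed on soma-to-tip paths; paths whose total
  excursion does not exceed one mean step are excluded from per-cell
  means, mirroring the fact that the measure is not always defined.
  Window sizes are counted in steps with lengths normalized by the mean
  step, which is exact for the engine's near-uniform segments and an
  approximation for strongly length-modulated trees.
- **Partition asymmetry**: mean over the n−1 bifurcations of
  |r−s|/(r+s−2) on terminal-segment counts (0 when r = s = 1); 0 for
  balanced trees, (n−2)/(n−1) for caterpillars. Only binary trees are
  accepted; the multi-stem soma root is not a bifurcation.
- **Sholl profile**: segment crossings of concentric shells, default 20
  equal steps from the soma radius to the farthest tip; a segment crossing
  k shells counts in each.
- **Branch order** is centrifugal with stems at order 0.

All measures are invariant under rigid motion (tested) and all I/O goes
through the SWC layer (single-point soma of type 1, dendrites type 3,
radii — not diameters — in column 6).

## Packaged configurations and what they emulate

`baseline.cfg` encodes the 2-D force-sweep protocol: all three forces at
strength 1 in a 150 × 100 μm rectangle, eight stems, constant radius
(`ralls_ratio 2`, no taper) so that termination is purely spatial, and a
branching probability of 0.077 μm⁻¹ — the value implied by the nearly
constant bifurcations-per-length ratio across the three published sweep
conditions. σ = 0.8, decays (soma-tropic 0.5, self-avoidance 2) and
proximity 0.2 μm are calibrated once, since the sweep's auxiliary
parameters are not published; with them, raising one force to 50
reproduces the qualitative regimes: strong soma-tropism gives straight
radial dendrites (population contraction ≈ 0.99), strong self-avoidance
gives the densest, longest arbors, and mean length/branch counts rise
monotonically from baseline through soma-tropic to self-avoidance.
Absolute sizes are matched only in order of magnitude; the contraction
statistics are the quantitative anchors.

`granule.cfg`, `motor_neuron.cfg` and `purkinje.cfg` are cell-type
lookalikes: force values that are published (granule: avoidance 4.5,
inertia 0.45, flatness 0.03; Purkinje: avoidance 5.4, inertia 0.32,
flatness 0, an order-of-magnitude larger branching probability, negative
front extension, unequal daughters; motor: forces inside the published
ranges) are copied; everything else is calibrated. The granule population
lands at ~14 tips / ~13 bifurcations and ~1.2 mm total length; the
Purkinje configuration reproduces the trunk-dominated, high-order planar
arbor qualitatively but remains more tortuous (contraction ≈ 0.64 vs
≈ 0.74) and more asymmetric than the reference — a known limitation of the
uniform branching rule. Generated cells emulate single-soma dendritic
trees only: no axons, spines, heterotypic interactions, tissue packing or
the two-plane Purkinje phenomenon; agreement on these synthetic
populations does not by itself establish agreement with reconstructions.

## Problem sizes

The test suite and the acceptance script use 25-seed populations for the
sweep and granule protocols, 100 walks of 10⁴ steps for the random-walk
limit of D, 10⁵ draws for sampling-moment and branching-law oracles, and
10⁵/2·10⁴ draws for the isotropy/concentration checks of the direction
sampler; each was chosen as the smallest ensemble whose Monte-Carlo error
is comfortably below the tolerance it is tested against.

## Known limitations

- The uniform branching probability flattens the branch-order
  distribution relative to real cells (visible in the Purkinje lookalike).
- Self-avoidance is midpoint-based; very long segments under-resolve the
  repulsion field.
- The adaptive stem schedule guarantees feasibility, not maximal angular
  spread; for nbr_stems ≫ 10 stems can cluster.
- 2-D mode treats the bounding rectangle as infinite in z; use `box` for
  a true 3-D bound.
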