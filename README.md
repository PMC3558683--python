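# dendrogen

Stochastic generation of virtual dendritic morphologies shaped entirely by
*homotypic* (self-referential) growth biases, plus the morphometric suite
needed to compare generated cells with reconstructions.

## The model

Dendritic arbors are grown front by front. Topology follows a **modified
Galton–Watson process**: after every segment of length *L*, the active tip
bifurcates with probability

> P(branch) = 1 − exp(−p·L)

where *p* is a global branching probability per micrometre. Geometry comes
from sampling each growth direction from a 3-D Gaussian (drawn with
Marsaglia's polar method, standard deviation σ, z-dimension scaled by a
*flatness* factor — 0 yields strictly planar cells) whose **mean is displaced
by the sum of three homotypic force vectors**:

- **inertial** — continuation of the previous segment, modelling membrane
  and cytoskeletal stiffness: `k_i · d_prev`;
- **soma-tropic** — radial bias along the soma-to-tip axis, decaying with
  distance: `k_s / d^γ_s · û`; positive strength pushes away from the soma;
- **self-avoidance** — summed repulsion from the midpoints of all existing
  segments of the same neuron: `k_a · Σ û_j / d_j^γ_a`.

Only the *direction* of the displaced sample is kept, so strong forces bias
but never fully determine growth. Branches terminate, in priority order, on
minimum radius, on surface-to-surface proximity to another branch, or on
collision with a bounding shape; the neuron stops when all fronts have
terminated or a total-fiber-length or bifurcation cap is reached. Daughter
radii satisfy `r₁ + r₂ = ralls_ratio · r_parent` with an optional unequal
split, radii taper exponentially, and segment length can scale with radius
(`front_extension`) to modulate branching frequency across the tree.

Analysis covers total length, bifurcation/tip counts, tip-path
**contraction** (Euclidean over path distance), per-branch **Hausdorff
fractal dimension** (structure-function estimate of D in ⟨E⟩^D = t; 1 for
straight paths, 2 for planar random walks), **van Pelt partition
asymmetry**, centrifugal branch orders, soma-to-tip path lengths and
**Sholl profiles**. Morphologies are written and read as classic 7-column
SWC.

## Worked example

Grow one granule-cell-like neuron from the packaged configuration and
measure it:

```sh
$ dendrogen grow --config src/dendrogen/configs/granule.cfg --seed 42 --out granule_42.swc
grow seed=42 config_hash=e410525e7e4d n_nodes=832 terminations=[boundary=19] wall_s=0.15

$ dendrogen measure granule_42.swc --format json
```

which reports, among other fields:

| metric | value | meaning |
| --- | --- | --- |
| `total_length` | 1668.0 | μm of dendrite grown |
| `n_tips` / `n_bifurcations` | 19 / 17 | binary-tree identity: tips = bifurcations + stems (2) |
| `contraction_mean` | 0.897 | tip paths are close to straight (1 = perfectly straight) |
| `fractal_dimension_mean` | 1.026 | near-linear branches, typical of granule cells |
| `partition_asymmetry` | 0.594 | moderately unbalanced dendrogram (0 balanced … 1 chain-like) |
| `path_length_mean` | 191.5 | mean soma-to-tip path, μm |

All 19 branches here terminated on the bounding sphere (`boundary=19`),
i.e. at the outer edge of the molecular-layer-sized growth domain. Growth
is a pure function of (configuration, seed): the same invocation always
produces byte-identical SWC. Other entry points: `dendrogen population`
(seed-varied populations with mean ± sd summaries), `dendrogen sweep`
(vary one parameter across populations), `dendrogen measure` (existing SWC
reconstructions). Packaged configurations: `baseline.cfg` (force-sweep
reference), `motor_neuron.cfg`, `granule.cfg`, `purkinje.cfg`.

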