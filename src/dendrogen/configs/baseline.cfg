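# Baseline force-sweep condition: all three homotypic forces at strength 1,
# 2-D growth inside a 150 x 100 um bounding rectangle.  Radius is constant
# (ralls_ratio 2, no taper), so branches terminate on proximity to other
# branches or on the boundary; the branching probability per micrometre is
# shared by the whole sweep.
self_avoidance_force 1
self_avoidance_decay 2
soma_tropic_force 1
soma_tropic_decay 0.5
inertial_force 1
branch_probability 0.077
front_extension 0
bounding_shape rectangle 150 100
intersection_proximity 0.2
max_fiber_length 50000
max_bifurcations 100000
min_radius 0.05
nbr_stems 8
start_radius 0.25
taper_rate 0
ralls_ratio 2
angle_limit 0.5 1.5
flatness 0
sigma 0.8
base_segment_length 2
daughter_asymmetry 0.5
seed 1
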