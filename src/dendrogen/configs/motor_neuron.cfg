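# Alpha-motor-neuron lookalike: fully 3-D, very strong soma-tropism that
# falls off rapidly (1/d^2), weak self-avoidance, moderate inertia, ten
# stems, tapering radii.  Forces inside the ranges reported for this cell
# type; auxiliary values are calibrated.
self_avoidance_force 0.2
self_avoidance_decay 2
soma_tropic_force 300
soma_tropic_decay 2
inertial_force 0.6
branch_probability 0.004
front_extension 0
bounding_shape sphere 900
intersection_proximity 0.3
max_fiber_length 30000
max_bifurcations 100000
min_radius 0.1
nbr_stems 10
start_radius 2
taper_rate 0.0008
ralls_ratio 1.6
angle_limit 0.5 1.5
flatness 1
sigma 0.08
base_segment_length 5
daughter_asymmetry 0.5
seed 1
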