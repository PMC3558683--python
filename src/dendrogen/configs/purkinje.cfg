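# Cerebellar Purkinje-cell lookalike: strictly planar (flatness 0), the
# strongest self-avoidance (5.4) and weakest inertia (0.32) of the packaged
# types, an order-of-magnitude higher branching probability, negative front
# extension (segments shorten as radii taper, raising branching frequency
# outward) and unequal daughter radii that preserve a main trunk.
self_avoidance_force 5.4
self_avoidance_decay 2
soma_tropic_force 8
soma_tropic_decay 1
inertial_force 0.32
branch_probability 0.1
front_extension -0.3
bounding_shape rectangle 200 200
intersection_proximity 0.4
max_fiber_length 50000
max_bifurcations 100000
min_radius 0.15
nbr_stems 1
start_radius 2.5
taper_rate 0.008
ralls_ratio 1.7
angle_limit 0.4 1.2
flatness 0
sigma 0.1
base_segment_length 3
daughter_asymmetry 0.62
seed 1
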