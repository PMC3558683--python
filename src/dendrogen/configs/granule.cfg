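# Dentate gyrus granule-cell lookalike: strong soma-tropism with a gradual
# (1/d) fall-off, self-avoidance 4.5, inertia 0.45, nearly flat (flatness
# 0.03).  The remaining values are calibrated, not measured.
self_avoidance_force 4.5
self_avoidance_decay 2
soma_tropic_force 60
soma_tropic_decay 1
inertial_force 0.45
branch_probability 0.01
front_extension 0
bounding_shape sphere 170
intersection_proximity 0.3
max_fiber_length 50000
max_bifurcations 100000
min_radius 0.05
nbr_stems 2
start_radius 0.4
taper_rate 0
ralls_ratio 2
angle_limit 0.5 1.5
flatness 0.03
sigma 0.3
base_segment_length 2
daughter_asymmetry 0.5
seed 1
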