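# Force-sweep experiment: vary one homotypic force while the other two stay
# at strength 1 (the baseline condition), 25 seeds per setting.
config: baseline.cfg
axis: self_avoidance_force
values: [1, 5, 50]
seeds_per_cell: 25
seed0: 1
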