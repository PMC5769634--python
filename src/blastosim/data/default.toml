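# Frozen default configuration. Calibrated so that a two-cell system relaxes
# to its equilibrium separation well within one inter-division interval; the
# eggshell volume matches a sphere of radius 20 um.

[eggshell]
volume_um3 = 33510.321638291124

[cells]
volume_fraction = 0.90     # total cell volume / eggshell volume
ab_volume_fraction = 0.55  # AB share of the embryo at the two-cell stage

[forces]
F0 = 0.5
shell_gain = 1.0
default_alpha = 0.75

[forces.alpha_pairs]
"EMS-P2" = 0.90

[integration]
dt_s = 5.0
noise_variance_um2 = 0.027

[division]
t_first_s = 300.0
stagger_s = 120.0
ab_daughter_fraction = 0.5
p1_daughter_fraction = 0.55
placement_offset_um = 2.0
settle_s = 600.0

[sweep]
ar_min = 1.0
ar_max = 4.0
ar_step = 0.1
n_reps = 30
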