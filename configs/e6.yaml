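# Mid-stage preset: the dual population peaks (~4% of cells) and spans the
# full CT-to-muscle trajectory.
seed: 6
sim:
  biphasic_mode: late
  dual_fraction: 0.04
  n_cells_per_population: {CT: 1000, M: 1000, OTHER_1: 450, OTHER_2: 420, OTHER_3: 420}
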