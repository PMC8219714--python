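# Late-stage preset: larger dataset, dual population maintained (~3.3%).
seed: 10
sim:
  biphasic_mode: late
  dual_fraction: 0.033
  n_cells_per_population: {CT: 6900, M: 6900, OTHER_1: 3100, OTHER_2: 2900, OTHER_3: 2900}
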