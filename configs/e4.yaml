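# Early progenitor stage preset: a very small dual population whose muscle
# markers are rising while CT markers are still fully expressed.
# The mapping of simulator defaults to real stages is illustrative.
seed: 4
sim:
  biphasic_mode: early
  dual_fraction: 0.005
  n_cells_per_population: {CT: 1450, M: 1450, OTHER_1: 680, OTHER_2: 630, OTHER_3: 630}
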