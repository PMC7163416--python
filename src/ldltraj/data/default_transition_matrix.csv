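state,ON_TARGET,OFF_LT_0_5,OFF_0_5_0_9,OFF_1_0_1_4,OFF_1_5_1_9,OFF_GE_2_0
ON_TARGET,0.84,0.10,0.03,0.01,0.01,0.01
OFF_LT_0_5,0.30,0.52,0.12,0.04,0.02,0.01
OFF_0_5_0_9,0.23,0.19,0.43,0.09,0.03,0.02
OFF_1_0_1_4,0.20,0.12,0.16,0.39,0.08,0.05
OFF_1_5_1_9,0.19,0.13,0.11,0.12,0.36,0.10
OFF_GE_2_0,0.15,0.13,0.09,0.10,0.09,0.43
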