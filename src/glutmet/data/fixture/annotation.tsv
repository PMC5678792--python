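sample	group	cohort
SIM1_C001	cancer	SIM1
SIM1_C002	cancer	SIM1
SIM1_C003	cancer	SIM1
SIM1_C004	cancer	SIM1
SIM1_C005	cancer	SIM1
SIM1_C006	cancer	SIM1
SIM1_C007	cancer	SIM1
SIM1_C008	cancer	SIM1
SIM1_C009	cancer	SIM1
SIM1_C010	cancer	SIM1
SIM1_C011	cancer	SIM1
SIM1_C012	cancer	SIM1
SIM1_N001	control	SIM1
SIM1_N002	control	SIM1
SIM1_N003	control	SIM1
SIM1_N004	control	SIM1
SIM1_N005	control	SIM1
SIM1_N006	control	SIM1
SIM1_N007	control	SIM1
SIM1_N008	control	SIM1
SIM1_N009	control	SIM1
SIM1_N010	control	SIM1
SIM1_N011	control	SIM1
SIM1_N012	control	SIM1
SIM2_C001	cancer	SIM2
SIM2_C002	cancer	SIM2
SIM2_C003	cancer	SIM2
SIM2_C004	cancer	SIM2
SIM2_C005	cancer	SIM2
SIM2_C006	cancer	SIM2
SIM2_C007	cancer	SIM2
SIM2_C008	cancer	SIM2
SIM2_C009	cancer	SIM2
SIM2_C010	cancer	SIM2
SIM2_C011	cancer	SIM2
SIM2_C012	cancer	SIM2
SIM2_N001	control	SIM2
SIM2_N002	control	SIM2
SIM2_N003	control	SIM2
SIM2_N004	control	SIM2
SIM2_N005	control	SIM2
SIM2_N006	control	SIM2
SIM2_N007	control	SIM2
SIM2_N008	control	SIM2
SIM2_N009	control	SIM2
SIM2_N010	control	SIM2
SIM2_N011	control	SIM2
SIM2_N012	control	SIM2
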