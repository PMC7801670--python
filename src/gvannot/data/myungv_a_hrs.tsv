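label	start	end
hr1	38812	39431
hr2	49441	49811
hr3	64322	64816
hr4	70464	71122
hr5	108728	109096
hr5a	113797	113923
hr6	151030	151402
hr7	163796	164430
hr8	169581	169956
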