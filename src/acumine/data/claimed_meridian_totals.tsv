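meridian	claimed_frequency	claimed_acupoint_number
LI	90	12
ST	89	20
BL	88	22
DU	71	18
RN	70	14
GB	67	14
SP	39	6
SJ	20	6
PC	17	4
KI	12	2
LR	11	2
LU	8	5
SI	7	4
HT	4	2
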