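raw	code
Tianchi (PC 2)	PC1
Tianshu (BL 10)	BL10
Shenshu (DU 12)	DU12
Wailiing	ST26
Wailiing (ST 26)	ST26
Zhongzhu (SJ 3)	SJ3
Futu (ST 32)	ST32
Futu (LI 18)	LI18
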