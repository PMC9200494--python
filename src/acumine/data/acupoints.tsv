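code	pinyin	meridian	region	frequency
ST36	Zusanli	ST	lower-limbs	28
SP6	Sanyinjiao	SP	lower-limbs	20
GB34	Yanglingquan	GB	lower-limbs	19
ST41	Jiexi	ST	lower-limbs	11
KI3	Taixi	KI	lower-limbs	11
ST32	Futu	ST	lower-limbs	10
LR3	Taichong	LR	lower-limbs	9
SP10	Xuehai	SP	lower-limbs	8
ST31	Biguan	ST	lower-limbs	8
ST34	Liangqiu	ST	lower-limbs	8
SP9	Yinlingquan	SP	lower-limbs	7
BL40	Weizhong	BL	lower-limbs	6
GB41	Zulinqi	GB	lower-limbs	6
GB30	Huantiao	GB	lower-limbs	5
BL60	Kunlun	BL	lower-limbs	5
ST40	Fenglong	ST	lower-limbs	4
GB31	Fengshi	GB	lower-limbs	4
GB39	Xuanzhong	GB	lower-limbs	3
ST38	Tiaokou	ST	lower-limbs	2
ST43	Xiangu	ST	lower-limbs	2
BL57	Chengshan	BL	lower-limbs	2
ST44	Neiting	ST	lower-limbs	2
ST42	Chongyang	ST	lower-limbs	1
ST37	Shangjuxu	ST	lower-limbs	1
ST35	Dubi	ST	lower-limbs	1
KI1	Yongquan	KI	lower-limbs	1
GB43	Jiaxi	GB	lower-limbs	1
SP4	Gongsun	SP	lower-limbs	1
SP3	Taibai	SP	lower-limbs	1
GB40	Qiuxu	GB	lower-limbs	1
EX-LE2	Heding	EX	lower-limbs	1
LI4	Hegu	LI	upper-limbs	28
LI11	Quchi	LI	upper-limbs	22
PC6	Neiguan	PC	upper-limbs	14
LI10	Shousanli	LI	upper-limbs	13
LI15	Jianyu	LI	upper-limbs	13
SJ5	Waiguan	SJ	upper-limbs	10
LI5	Yangxi	LI	upper-limbs	4
HT1	Jiquan	HT	upper-limbs	3
SJ3	Zhongzhu	SJ	upper-limbs	3
LU10	Yuji	LU	upper-limbs	3
LU5	Chize	LU	upper-limbs	2
LI3	Sanjian	LI	upper-limbs	2
LI13	Shouwuli	LI	upper-limbs	2
LI14	Binao	LI	upper-limbs	2
LI6	Pianli	LI	upper-limbs	1
LI7	Wenliu	LI	upper-limbs	1
LI2	Erjian	LI	upper-limbs	1
HT8	Shaofu	HT	upper-limbs	1
PC3	Quze	PC	upper-limbs	1
PC8	Laogong	PC	upper-limbs	1
LU9	Taiyuan	LU	upper-limbs	1
SI3	Houxi	SI	upper-limbs	1
SI9	Jianzhen	SI	upper-limbs	1
SJ14	Jianliao	SJ	upper-limbs	1
SJ2	Yemen	SJ	upper-limbs	1
SJ10	Tianjing	SJ	upper-limbs	1
EX-UE9	Baxie	EX	upper-limbs	1
EX-B2	Jiaji	EX	back-lumbar	15
BL23	Shenshu	BL	back-lumbar	14
BL18	Ganshu	BL	back-lumbar	13
BL20	Pishu	BL	back-lumbar	12
BL21	Weishu	BL	back-lumbar	6
DU4	Mingmen	DU	back-lumbar	6
GB21	Jianjing	GB	back-lumbar	5
DU3	Yaoyangguan	DU	back-lumbar	4
SI11	Tianzong	SI	back-lumbar	4
BL13	Feishu	BL	back-lumbar	4
BL15	Xinshu	BL	back-lumbar	4
BL17	Geshu	BL	back-lumbar	3
DU12	Shenzhu	DU	back-lumbar	3
DU7	Zhongshu	DU	back-lumbar	2
DU8	Jinsuo	DU	back-lumbar	2
DU9	Zhiyang	DU	back-lumbar	2
DU11	Shendao	DU	back-lumbar	2
DU6	Jizhong	DU	back-lumbar	2
DU1	Changqiang	DU	back-lumbar	2
DU2	Yaoshu	DU	back-lumbar	2
BL42	Pohu	BL	back-lumbar	1
BL44	Shentang	BL	back-lumbar	1
BL26	Guanyuanshu	BL	back-lumbar	1
BL32	Ciliao	BL	back-lumbar	1
BL54	Zhibian	BL	back-lumbar	1
BL46	Geguan	BL	back-lumbar	1
EX-B1	Dingchuan	EX	back-lumbar	1
DU10	Lingtai	DU	back-lumbar	1
DU13	Taodao	DU	back-lumbar	1
GB20	Fengchi	GB	head-face-neck	13
DU20	Baihui	DU	head-face-neck	12
DU14	Dazhui	DU	head-face-neck	12
RN23	Lianquan	RN	head-face-neck	11
DU26	Shuigou	DU	head-face-neck	6
DU24	Shenting	DU	head-face-neck	5
EX-HN12	Jinjin	EX	head-face-neck	5
EX-HN13	Yuye	EX	head-face-neck	5
GB12	Wangu	GB	head-face-neck	5
DU16	Fengfu	DU	head-face-neck	4
BL10	Tianzhu	BL	head-face-neck	4
SJ17	Yifeng	SJ	head-face-neck	4
DU15	Yamen	DU	head-face-neck	3
EX-HN1	Sishencong	EX	head-face-neck	2
RN22	Tiantu	RN	head-face-neck	2
RN24	Chengjiang	RN	head-face-neck	2
LI18	Futu	LI	head-face-neck	1
ST6	Jiache	ST	head-face-neck	1
ST8	Touwei	ST	head-face-neck	2
ST7	Xiaguan	ST	head-face-neck	2
ST12	Quepen	ST	head-face-neck	1
BL8	Luoque	BL	head-face-neck	1
BL7	Tongtian	BL	head-face-neck	1
BL6	Chengguang	BL	head-face-neck	1
BL5	Wuchu	BL	head-face-neck	1
GB6	Xuanli	GB	head-face-neck	1
GB7	Qubin	GB	head-face-neck	1
GB15	Toulinqi	GB	head-face-neck	1
SI17	Tianrong	SI	head-face-neck	1
EX-HN3	Yintang	EX	head-face-neck	1
EX-HN10	Juquan	EX	head-face-neck	1
EX-HN20	Shanglianquan	EX	head-face-neck	1
RN6	Qihai	RN	chest-abdomen	14
RN12	Zhongwan	RN	chest-abdomen	13
RN4	Guanyuan	RN	chest-abdomen	11
RN17	Danzhong	RN	chest-abdomen	6
RN10	Xiawan	RN	chest-abdomen	5
ST25	Tianshu	ST	chest-abdomen	4
ST30	Qichong	ST	chest-abdomen	3
LR13	Zhangmen	LR	chest-abdomen	2
SP15	Daheng	SP	chest-abdomen	2
ST26	Wailing	ST	chest-abdomen	1
ST24	Huaroumen	ST	chest-abdomen	2
RN3	Zhongji	RN	chest-abdomen	1
RN13	Shangwan	RN	chest-abdomen	1
RN9	Shuifen	RN	chest-abdomen	1
RN14	Juque	RN	chest-abdomen	1
RN18	Yutang	RN	chest-abdomen	1
RN7	Yinjiao	RN	chest-abdomen	1
GB27	Wushu	GB	chest-abdomen	1
GB28	Weidao	GB	chest-abdomen	1
LU1	Zhongfu	LU	chest-abdomen	1
LU2	Yunmen	LU	chest-abdomen	1
PC1	Tianchi	PC	chest-abdomen	1
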