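locus	allele
A	A*01:01
A	A*02:01
A	A*02:05
A	A*03:01
A	A*11:01
A	A*23:01
A	A*24:02
A	A*26:01
A	A*29:02
A	A*30:01
A	A*31:01
A	A*32:01
A	A*33:03
A	A*68:01
B	B*07:02
B	B*08:01
B	B*15:01
B	B*18:01
B	B*27:05
B	B*35:01
B	B*40:01
B	B*44:02
B	B*51:01
B	B*57:01
C	C*01:02
C	C*03:04
C	C*04:01
C	C*05:01
C	C*06:02
C	C*07:01
C	C*07:02
C	C*12:03
C	C*15:02
C	C*16:01
DRB1	DRB1*01:01
DRB1	DRB1*03:01
DRB1	DRB1*04:01
DRB1	DRB1*04:02
DRB1	DRB1*04:03
DRB1	DRB1*04:04
DRB1	DRB1*04:05
DRB1	DRB1*07:01
DRB1	DRB1*08:01
DRB1	DRB1*09:01
DRB1	DRB1*11:01
DRB1	DRB1*13:01
DRB1	DRB1*14:01
DRB1	DRB1*15:01
DRB1	DRB1*15:03
DRB1	DRB1*16:01
DQA1	DQA1*01:01
DQA1	DQA1*01:02
DQA1	DQA1*01:03
DQA1	DQA1*02:01
DQA1	DQA1*03:01
DQA1	DQA1*03:03
DQA1	DQA1*04:01
DQA1	DQA1*05:01
DQA1	DQA1*05:05
DQA1	DQA1*06:01
DQB1	DQB1*02:01
DQB1	DQB1*02:02
DQB1	DQB1*03:01
DQB1	DQB1*03:02
DQB1	DQB1*03:03
DQB1	DQB1*04:02
DQB1	DQB1*05:01
DQB1	DQB1*05:02
DQB1	DQB1*06:02
DQB1	DQB1*06:03
DPB1	DPB1*01:01
DPB1	DPB1*02:01
DPB1	DPB1*03:01
DPB1	DPB1*04:01
DPB1	DPB1*04:02
DPB1	DPB1*05:01
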