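code,category
CHD01,CHD
CHD02,CHD
STR01,STROKE
STR02,STROKE
PAD01,PAD
PAD02,PAD
AAA01,AAA
DM01,DIABETES
CKD01,CKD
DIA01,DIALYSIS
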