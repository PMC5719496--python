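mz	mz_text	lipid_id	isotope_flag	category
635.6			0	EQ
645.6			0	IMS_LT
681.5			0	IMS_LLT
697.4	697.35	Phospholipid	0	IMS_GT
698.4			0	IMS_LLT
712.4	712.3	Phospholipid	0	EQ
713.6	713.75	Phospholipid	0	IMS_GT
714.6			1	IMS_GGT
728.3	728.2	Phospholipid	0	IMS_GT
729.3	729.22	Phospholipid	0	IMS_GGT
834.7	834.67	PS(40:6)	0	IMS_GGT
883.7		PI(38:5)	0	IMS_LT
884.7			1	EQ
885.7	885.62	PI(38:4)	0	EQ
886.7	886.64	PI(38:3)	0	IMS_LT
887.7		Phospholipid	0	IMS_LT
888.7	888.65	ST(24:1)	0	IMS_LLT
889.7			1	IMS_LLT
890.7	890.66	ST(24:0)	0	IMS_LLT
905.4			1	IMS_GT
906.4		ST(24:0)(OH)	0	IMS_LLT
907.4		Phospholipid	0	IMS_LT
912.8		PI(40:4)	0	IMS_LT
913.7			1	EQ
923.3			0	IMS_GT
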