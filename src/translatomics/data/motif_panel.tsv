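# Default RNA-binding-protein motif panel (28 motif x region scores).
# Consensus strings are IUPAC, RNA space. This panel is a reconstruction
# assembled from published yeast RBP consensus elements; it is the single
# source of truth for the motif block of the default feature schema and is
# user-replaceable.
name	consensus_or_pwm	target_region	scoring
Puf3_3utr	CYUGUAAAUA	utr3	count
Puf3_5utr	CYUGUAAAUA	utr5	count
Puf1_3utr	UAAUAAU	utr3	count
Puf1_5utr	UAAUAAU	utr5	count
Puf2_3utr	UAAUNNUAAU	utr3	count
Puf2_5utr	UAAUNNUAAU	utr5	count
Puf4_3utr	UGUAUAUUA	utr3	count
Puf4_5utr	UGUAUAUUA	utr5	count
Puf5_3utr	UGUANNNAUA	utr3	count
Puf5_5utr	UGUANNNAUA	utr5	count
Pab1_3utr	AAAAAAA	utr3	count
Pab1_5utr	AAAAAAA	utr5	count
Pub1_3utr	UUUUUUU	utr3	count
Pub1_5utr	UUUUUUU	utr5	count
Hrp1_3utr	UAUAUA	utr3	count
Hrp1_5utr	UAUAUA	utr5	count
Nrd1_3utr	UGUAG	utr3	count
Nrd1_5utr	UGUAG	utr5	count
Nab3_3utr	UCUUG	utr3	count
Nab3_5utr	UCUUG	utr5	count
Vts1_3utr	CUGGC	utr3	count
Vts1_5utr	CUGGC	utr5	count
Whi3_3utr	UGCAU	utr3	count
Whi3_5utr	UGCAU	utr5	count
Khd1_3utr	CAUCAU	utr3	count
Khd1_5utr	CAUCAU	utr5	count
Nsr1_3utr	AGGGA	utr3	count
Nsr1_5utr	AGGGA	utr5	count
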