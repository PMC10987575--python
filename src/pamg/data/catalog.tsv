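kind	ko_ids	category	previously_reported
ppa	K01507	solubilization	1
ppx	K01524	solubilization	0
phnP	K06167	mineralization	0
phnW	K03430	mineralization	0
phoD	K01113	mineralization	1
ugpQ	K01126	mineralization	0
phnD	K02044	transporter	1
pit	K03306	transporter	0
pstS	K02040	transporter	1
pstA	K02038	transporter	0
pstB	K02036	transporter	0
pstC	K02037	transporter	0
ugpE	K05815	transporter	0
yjbB	K03324	transporter	1
phoB	K07657	regulator	1
phoR	K07636	regulator	0
phoU	K02039	regulator	0
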