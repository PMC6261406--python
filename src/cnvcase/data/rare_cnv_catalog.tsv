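chrom	start	end	genes	cnv_type	size_kb	sample_id	pop_freq
1	196964969	196987806	CFHR5	loss	23	SLE005	-
2	34219274	34313413	-	loss	94	SLE009	< 1%
2	36932842	36964864	VIT	loss	32	SLE010	-
3	65517399	65595008	MAGI1	gain	78	SLE015	< 1%
5	96625630	96865984	-	loss	240	SLE014	-
6	152303218	152311895	ESR1	loss	9	SLE003	< 1%
7	11983316	12078163	-	gain	95	SLE005	< 1%
7	85522989	85709099	-	loss	186	SLE003	< 1%
7	114209440	114215739	FOXP2	loss	6	SLE023	-
7	146859536	146868357	CNTNAP2	loss	9	SLE003	-
8	30079990	30202711	MIR548O2	gain	123	SLE018	-
9	137354612	137529641	-	gain	175	SLE023	< 1%
12	21796951	22445614	LDHB,KCNJ8,ABCC9,CMAS,ST8SIA1	gain	649	SLE018	< 1%
13	93378273	93386333	GPC5	loss	8	SLE023	-
13	94506273	94515199	GPC6,GPC6-AS2	loss	9	SLE023	< 1%
13	104521177	104647267	-	loss	126	SLE013	-
14	67111441	67148873	GPHN	gain	37	SLE011	-
14	67193022	67217571	GPHN	loss	25	SLE016	< 1%
22	25066486	25112325	-	loss	46	SLE006	< 1%
X	15723836	15831401	CA5B,INE2,ZRSR2	gain	108	SLE018	-
X	52833688	52904643	XAGE5,XAGE3	gain	71	SLE017	-
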