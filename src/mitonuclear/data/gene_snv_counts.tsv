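gene	genome_class	chrom	start	end	n_snvs
MT-ND3	mitochondrial	MT	10059	10404	77
MT-ATP6	mitochondrial	MT	8527	9207	226
MT-ATP8	mitochondrial	MT	8366	8572	73
MT-CO1	mitochondrial	MT	5904	7445	319
MT-CO2	mitochondrial	MT	7586	8269	152
MT-CO3	mitochondrial	MT	9207	9990	182
MT-CYB	mitochondrial	MT	14747	15887	326
MT-ND1	mitochondrial	MT	3307	4262	218
MT-ND2	mitochondrial	MT	4470	5511	236
MT-ND4	mitochondrial	MT	10760	12137	291
MT-ND5	mitochondrial	MT	12337	14148	408
MT-ND6	mitochondrial	MT	14149	14673	128
MT-RNR1	mitochondrial	MT	648	1601	118
ADRA1A	nuclear	8	26738113	26870994	7311
ADRB3	nuclear	8	37962990	37966599	203
CIDEA	nuclear	18	12254361	12277595	1445
CREB1	nuclear	2	207529943	207605988	4353
DIO2	nuclear	14	80197526	80231057	10223
FTO	nuclear	16	53703963	54121941	23729
HOXC4	nuclear	12	54016888	54056030	1801
HOXA1	nuclear	7	27092993	27096000	149
LIPE	nuclear	19	42401512	42427421	1485
LEP	nuclear	7	128241201	128257629	863
LEPR	nuclear	1	65420652	65641559	11705
NRF1	nuclear	7	129611720	129757082	6949
NRIP1	nuclear	21	14961235	15065903	753
PLIN1	nuclear	15	89664365	89679367	865
PLIN2	nuclear	9	19108391	19127606	2751
PLIN3	nuclear	19	4838341	4867667	2141
PLIN5	nuclear	19	4522531	4535224	999
PPARG	nuclear	3	12287368	12434344	7539
PPARGC1A	nuclear	4	23792021	24472905	5581
PPARGC1B	nuclear	5	149730302	149857861	7307
PRDM16	nuclear	1	3069203	3438621	28237
PRKAR1A	nuclear	17	68413623	68551316	1869
PRKAR2A	nuclear	3	48744601	48847874	4663
PRKAR1B	nuclear	7	549185	727676	14603
PRKAR2B	nuclear	7	107044705	107161811	6691
UCP1	nuclear	4	140555770	140568961	369
UCP2	nuclear	11	73974671	73983202	517
UCP3	nuclear	11	74000277	74009237	587
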