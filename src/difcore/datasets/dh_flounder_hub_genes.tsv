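gene	degree_f	kcore_f	degree_s	kcore_s	dif_kcore_published	direction
TGFB3	1	1	14	8	-7	up
SLC3A2	1	1	9	8	-7	up
CYP11A1	3	2	10	8	-6	down
DPP4	0	0	7	6	-6	up
CPA1	3	3	13	8	-5	up
CTSS	2	1	10	6	-5	up
BCL2L1	3	3	10	8	-5	down
CYP21A	1	1	7	6	-5	down
ABCA1	1	1	6	6	-5	up
CXCR3	10	8	15	9	-5	up
APOC1I	1	1	5	5	-4	up
CSF3R	4	4	10	8	-4	up
CYP17A1	3	3	8	6	-3	down
TNFSF10	3	3	7	6	-3	up
HSD3B	5	4	2	2	2	down
CXCL12A	11	11	9	8	3	up
CYP11B2	6	5	3	2	3	down
PRLR	8	5	1	1	4	down
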