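kmer	twist	tilt	roll	shift	slide	rise	enthalpy	entropy	free_energy	gc_content	purine_content	keto_content
AAA	35.6	-1.4	0.5	-0.03	-0.08	3.27	-7.9	-22.2	-1	0	1	0
AAC	35	-0.75	0.6	0.05	-0.33	3.315	-8.15	-22.3	-1.22	0.333333	0.666667	0
AAG	31.65	-1.55	2.5	0.03	-0.165	3.305	-7.85	-21.6	-1.14	0.333333	1	0.333333
AAT	33.55	-0.7	0.8	-0.015	-0.335	3.29	-7.55	-21.3	-0.94	0	0.666667	0.333333
ACA	34.45	0.2	2.7	0.11	-0.025	3.345	-8.45	-22.55	-1.445	0.333333	0.666667	0
ACC	34.05	-0.1	2.15	0.09	-0.4	3.39	-8.2	-21.15	-1.64	0.666667	0.333333	0
ACG	32.1	-0.05	3.05	0.065	-0.085	3.375	-9.5	-24.8	-1.805	0.666667	0.666667	0.333333
ACT	31.05	0.8	2.6	0.02	-0.415	3.35	-8.1	-21.7	-1.36	0.333333	0.333333	0.333333
AGA	32.3	-1.6	3.2	-0.095	-0.08	3.355	-8	-21.6	-1.29	0.333333	1	0.333333
AGC	33.85	-0.85	2.4	0.045	-0.315	3.37	-8.8	-22.7	-1.76	0.666667	0.666667	0.333333
AGG	30.7	-0.8	4.05	0.02	-0.235	3.38	-7.9	-20.45	-1.56	0.666667	1	0.666667
AGT	31.05	-0.8	2.6	-0.02	-0.415	3.35	-8.1	-21.7	-1.36	0.333333	0.666667	0.666667
ATA	33.75	0	2.2	0	-0.27	3.365	-7.2	-20.85	-0.73	0	0.666667	0.333333
ATC	34.2	0.75	1.5	0.14	-0.25	3.34	-7.7	-21.3	-1.09	0.333333	0.333333	0.333333
ATG	33	-0.25	2.9	-0.045	-0.03	3.32	-7.85	-21.55	-1.165	0.333333	0.666667	0.666667
ATT	33.55	0.7	0.8	0.015	-0.335	3.29	-7.55	-21.3	-0.94	0	0.333333	0.666667
CAA	35.05	-0.45	2.6	0.03	0.225	3.3	-8.2	-22.45	-1.225	0.333333	0.666667	0
CAC	34.45	0.2	2.7	0.11	-0.025	3.345	-8.45	-22.55	-1.445	0.666667	0.333333	0
CAG	31.1	-0.6	4.6	0.09	0.14	3.335	-8.15	-21.85	-1.365	0.666667	0.666667	0.333333
CAT	33	0.25	2.9	0.045	-0.03	3.32	-7.85	-21.55	-1.165	0.333333	0.333333	0.333333
CCA	34.1	0.2	4.15	0.07	0.155	3.375	-8.25	-21.3	-1.645	0.666667	0.333333	0
CCC	33.7	-0.1	3.6	0.05	-0.22	3.42	-8	-19.9	-1.84	1	0	0
CCG	31.75	-0.05	4.5	0.025	0.095	3.405	-9.3	-23.55	-2.005	1	0.333333	0.333333
CCT	30.7	0.8	4.05	-0.02	-0.235	3.38	-7.9	-20.45	-1.56	0.666667	0	0.333333
CGA	33.35	-0.75	3.65	-0.14	0.25	3.38	-9.4	-24.7	-1.735	0.666667	0.666667	0.333333
CGC	34.9	0	2.85	0	0.015	3.395	-10.2	-25.8	-2.205	1	0.333333	0.333333
CGG	31.75	0.05	4.5	-0.025	0.095	3.405	-9.3	-23.55	-2.005	1	0.666667	0.666667
CGT	32.1	0.05	3.05	-0.065	-0.085	3.375	-9.5	-24.8	-1.805	0.666667	0.333333	0.666667
CTA	31.85	0.85	3.9	-0.045	-0.1	3.38	-7.5	-21.15	-0.93	0.333333	0.333333	0.333333
CTC	32.3	1.6	3.2	0.095	-0.08	3.355	-8	-21.6	-1.29	0.666667	0	0.333333
CTG	31.1	0.6	4.6	-0.09	0.14	3.335	-8.15	-21.85	-1.365	0.666667	0.333333	0.666667
CTT	31.65	1.55	2.5	-0.03	-0.165	3.305	-7.85	-21.6	-1.14	0.333333	0	0.666667
GAA	36.25	-1.45	1.2	-0.155	0.005	3.32	-8.05	-22.2	-1.15	0.333333	1	0.333333
GAC	35.65	-0.8	1.3	-0.075	-0.245	3.365	-8.3	-22.3	-1.37	0.666667	0.666667	0.333333
GAG	32.3	-1.6	3.2	-0.095	-0.08	3.355	-8	-21.6	-1.29	0.666667	1	0.666667
GAT	34.2	-0.75	1.5	-0.14	-0.25	3.34	-7.7	-21.3	-1.09	0.333333	0.666667	0.666667
GCA	37.25	0.25	2.5	0.045	0.075	3.365	-9.15	-23.55	-1.845	0.666667	0.666667	0.333333
GCC	36.85	-0.05	1.95	0.025	-0.3	3.41	-8.9	-22.15	-2.04	1	0.333333	0.333333
GCG	34.9	0	2.85	0	0.015	3.395	-10.2	-25.8	-2.205	1	0.666667	0.666667
GCT	33.85	0.85	2.4	-0.045	-0.315	3.37	-8.8	-22.7	-1.76	0.666667	0.333333	0.666667
GGA	35.3	-0.7	2.75	-0.165	-0.065	3.395	-8.1	-21.05	-1.57	0.666667	1	0.666667
GGC	36.85	0.05	1.95	-0.025	-0.3	3.41	-8.9	-22.15	-2.04	1	0.666667	0.666667
GGG	33.7	0.1	3.6	-0.05	-0.22	3.42	-8	-19.9	-1.84	1	1	1
GGT	34.05	0.1	2.15	-0.09	-0.4	3.39	-8.2	-21.15	-1.64	0.666667	0.666667	1
GTA	35.2	0.05	2	-0.065	-0.265	3.39	-7.8	-21.85	-1.01	0.333333	0.666667	0.666667
GTC	35.65	0.8	1.3	0.075	-0.245	3.365	-8.3	-22.3	-1.37	0.666667	0.333333	0.666667
GTG	34.45	-0.2	2.7	-0.11	-0.025	3.345	-8.45	-22.55	-1.445	0.666667	0.666667	1
GTT	35	0.75	0.6	-0.05	-0.33	3.315	-8.15	-22.3	-1.22	0.333333	0.333333	1
TAA	35.8	-0.7	1.9	-0.015	-0.015	3.345	-7.55	-21.75	-0.79	0	0.666667	0.333333
TAC	35.2	-0.05	2	0.065	-0.265	3.39	-7.8	-21.85	-1.01	0.333333	0.333333	0.333333
TAG	31.85	-0.85	3.9	0.045	-0.1	3.38	-7.5	-21.15	-0.93	0.333333	0.666667	0.666667
TAT	33.75	0	2.2	0	-0.27	3.365	-7.2	-20.85	-0.73	0	0.333333	0.666667
TCA	35.7	1	3.3	0.185	0.31	3.35	-8.35	-22.45	-1.375	0.333333	0.333333	0.333333
TCC	35.3	0.7	2.75	0.165	-0.065	3.395	-8.1	-21.05	-1.57	0.666667	0	0.333333
TCG	33.35	0.75	3.65	0.14	0.25	3.38	-9.4	-24.7	-1.735	0.666667	0.333333	0.666667
TCT	32.3	1.6	3.2	0.095	-0.08	3.355	-8	-21.6	-1.29	0.333333	0	0.666667
TGA	35.7	-1	3.3	-0.185	0.31	3.35	-8.35	-22.45	-1.375	0.333333	0.666667	0.666667
TGC	37.25	-0.25	2.5	-0.045	0.075	3.365	-9.15	-23.55	-1.845	0.666667	0.333333	0.666667
TGG	34.1	-0.2	4.15	-0.07	0.155	3.375	-8.25	-21.3	-1.645	0.666667	0.666667	1
TGT	34.45	-0.2	2.7	-0.11	-0.025	3.345	-8.45	-22.55	-1.445	0.333333	0.333333	1
TTA	35.8	0.7	1.9	0.015	-0.015	3.345	-7.55	-21.75	-0.79	0	0.333333	0.666667
TTC	36.25	1.45	1.2	0.155	0.005	3.32	-8.05	-22.2	-1.15	0.333333	0	0.666667
TTG	35.05	0.45	2.6	-0.03	0.225	3.3	-8.2	-22.45	-1.225	0.333333	0.333333	1
TTT	35.6	1.4	0.5	0.03	-0.08	3.27	-7.9	-22.2	-1	0	0	1
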