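kmer	twist	tilt	roll	shift	slide	rise	enthalpy	entropy	free_energy	gc_content	purine_content	keto_content
AA	35.6	-1.4	0.5	-0.03	-0.08	3.27	-7.9	-22.2	-1.00	0.0	1.0	0.0
AC	34.4	-0.1	0.7	0.13	-0.58	3.36	-8.4	-22.4	-1.44	0.5	0.5	0.0
AG	27.7	-1.7	4.5	0.09	-0.25	3.34	-7.8	-21.0	-1.28	0.5	1.0	0.5
AT	31.5	0.0	1.1	0.00	-0.59	3.31	-7.2	-20.4	-0.88	0.0	0.5	0.5
CA	34.5	0.5	4.7	0.09	0.53	3.33	-8.5	-22.7	-1.45	0.5	0.5	0.0
CC	33.7	-0.1	3.6	0.05	-0.22	3.42	-8.0	-19.9	-1.84	1.0	0.0	0.0
CG	29.8	0.0	5.4	0.00	0.41	3.39	-10.6	-27.2	-2.17	1.0	0.5	0.5
CT	27.7	1.7	4.5	-0.09	-0.25	3.34	-7.8	-21.0	-1.28	0.5	0.0	0.5
GA	36.9	-1.5	1.9	-0.28	0.09	3.37	-8.2	-22.2	-1.30	0.5	1.0	0.5
GC	40.0	0.0	0.3	0.00	-0.38	3.40	-9.8	-24.4	-2.24	1.0	0.5	0.5
GG	33.7	0.1	3.6	-0.05	-0.22	3.42	-8.0	-19.9	-1.84	1.0	1.0	1.0
GT	34.4	0.1	0.7	-0.13	-0.58	3.36	-8.4	-22.4	-1.44	0.5	0.5	1.0
TA	36.0	0.0	3.3	0.00	0.05	3.42	-7.2	-21.3	-0.58	0.0	0.5	0.5
TC	36.9	1.5	1.9	0.28	0.09	3.37	-8.2	-22.2	-1.30	0.5	0.0	0.5
TG	34.5	-0.5	4.7	-0.09	0.53	3.33	-8.5	-22.7	-1.45	0.5	0.5	1.0
TT	35.6	1.4	0.5	0.03	-0.08	3.27	-7.9	-22.2	-1.00	0.0	0.0	1.0
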