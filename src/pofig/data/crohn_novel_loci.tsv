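# Scan, replication and combined two-sided P-values for the eleven newly
# identified Crohn's disease susceptibility loci with named candidate genes,
# transcribed from Barrett et al. (2008) Nature Genetics 40:955-962
# (genome-wide association meta-analysis of Crohn's disease).
id	gene	p	p_replication	p_combined
rs2476601	PTPN22	1.81e-5	1.0e-4	1.5e-8
rs2274910	ITLN1	3.5e-7	4.8e-4	1.5e-9
rs10045431	IL12B	8.80e-9	3.7e-6	3.9e-13
rs6908425	CDKAL1	2.5e-7	2.8e-4	9.0e-10
rs2301436	CCR6	3.3e-7	3.3e-7	1.0e-12
rs10758669	JAK2	6.8e-7	4.3e-4	3.5e-9
rs7927894	C11orf30	1.4e-7	7.3e-4	1.3e-9
rs11175593	LRRK2-MUC19	1.3e-7	1.6e-4	3.1e-10
rs2872507	ORMDL3	2.1e-6	2.9e-4	5.0e-9
rs744166	STAT3	5.9e-6	9.1e-8	6.8e-12
rs762421	ICOSLG	1.1e-5	1.6e-5	1.4e-9
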