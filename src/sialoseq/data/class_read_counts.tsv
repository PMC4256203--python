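class_label	n_cds	n_reads	printed_reads_per_cds	printed_pct_cds	printed_pct_reads
Secreted	2228	104622738	46958	19.91	48.94
Housekeeping	7281	103850665	14263	65.08	48.58
Transposable element	560	2092706	3737	5.01	0.98
Viral	47	990621	21077	0.42	0.46
Unknown	1072	2199892	2052	9.58	1.03
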