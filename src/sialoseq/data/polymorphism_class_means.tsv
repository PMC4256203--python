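class_label	mean_s_per_100	se_s	mean_ns_per_100	se_ns	printed_ns_s	n_cds
Extracellular matrix	1.047	0.092	0.484	0.053	0.462	180
Transporters	0.594	0.049	0.419	0.048	0.704	191
Signal transduction	0.555	0.028	0.406	0.03	0.731	677
Protein export	0.433	0.047	0.332	0.052	0.766	132
Protein modification	0.619	0.08	0.53	0.068	0.857	130
Detoxification	1.009	0.119	0.872	0.122	0.865	100
Cytoskeletal	0.511	0.051	0.451	0.056	0.882	139
Transcription factors	0.721	0.076	0.649	0.123	0.9	113
Nuclear export	0.098	0.023	0.096	0.023	0.976	18
Metabolism	0.669	0.043	0.666	0.051	0.995	496
Proteasome machinery	0.474	0.066	0.498	0.087	1.051	103
Unknown conserved	0.756	0.037	0.84	0.048	1.111	829
Transcription machinery	0.637	0.049	0.712	0.077	1.118	354
Nuclear regulation	0.875	0.094	0.98	0.096	1.12	277
Immunity	0.658	0.103	0.764	0.201	1.161	45
Viral	1.66	0.293	2.044	0.401	1.231	34
Storage	0.453	0.145	0.569	0.241	1.256	9
Transposable element	1.385	0.076	2.206	0.095	1.594	447
Unknown	1.223	0.098	2.229	0.135	1.823	306
Secreted	0.938	0.046	1.942	0.093	2.07	702
Protein synthesis	0.382	0.056	0.823	0.116	2.158	109
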