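library_id	stage	region	n_sequences	n_residues	printed_average_length	printed_median
Arg-A	adult	Arg	38060109	10385270028	272.9	300
Arg-N	nymph	Arg	39759543	11417825638	287.2	300
BolCol-A	adult	BolCol	38418718	10546661014	274.5	300
BolCol-N	nymph	BolCol	39223445	11258595763	287	300
BolNat-A	adult	BolNat	38573948	10165647571	263.5	300
BolNat-N	nymph	BolNat	48570803	13994680783	288.1	300
Chile-A	adult	Chile	34269672	9102400847	265.6	300
Chile-N	nymph	Chile	38866808	11069693781	284.8	300
Peru-A	adult	Peru	38540450	9775095017	253.6	300
Peru-N	nymph	Peru	41292975	11889399223	287.9	300
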