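species	assembly	pg4_bp	genome_ungapped_bp	est_starts_in_pg4	est_total	genes_with_intron_pg4	genes_total
human	hg38	10002935	2948583725	54397	8624218	14610	19014
chimpanzee	panTro6	9874095	3018592990	30	17848
mouse	mm10	16373835	2652767259	10786	4341907
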