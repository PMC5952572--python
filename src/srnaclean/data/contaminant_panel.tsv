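name	srna_sequence	avg_cpm_plasma	origin	primer_sequence	annealing_temp_C
sRNA 1	CTAACAGACCGAGGACTTGAAT	33700	algae	AACAGACCGAGGACTTGAA	57
sRNA 2	ACGGACAAGAATAGGCTTCGGCT	8000	fungi or plants	ACGGACAAGAATAGGCTTC	54
sRNA 3	GCCTTGGTTGTAGGATCTGT	8200	plants	GCCTTGGTTGTAGGATCTGT	57
sRNA 4	GCCAGCATCAGTTCGGTGTG	6800	bacteria	CAGCATCAGTTCGGTGTG	57
sRNA 5	GAGAGTAGGACGTTGCCAGGTT	3900	bacteria	AGTAGGACGTTGCCAGGTT	57
sRNA 6	TTGAAGGGTCGTTCGAGACCAGGACGTTGATAGGCTGGGTG	3400	bacteria	GAAGGGTCGTTCGAGACC	57
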