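chrom	arm	start	end
chr2	2p	0	93300000
chr2	2q	93300000	243199373
chr3	3p	0	91000000
chr3	3q	91000000	198022430
chr4	4p	0	50400000
chr4	4q	50400000	191154276
chr5	5p	0	48400000
chr5	5q	48400000	180915260
chr6	6p	0	61000000
chr6	6q	61000000	171115067
chr8	8p	0	45600000
chr8	8q	45600000	146364022
chr11	11p	0	53700000
chr11	11q	53700000	135006516
chr12	12p	0	35800000
chr12	12q	35800000	133851895
chr13	13q	17900000	115169878
chr17	17p	0	24000000
chr17	17q	24000000	81195210
chr19	19p	0	26500000
chr19	19q	26500000	59128983
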