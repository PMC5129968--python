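case	regions	chrom	start	end	mean_log2
MSS1	T1;T2;T3	chr5	111000000	113500000	-0.60
MSS3	T2	chr5	48500000	180900000	-0.55
MSS3	T3	chr5	111500000	112500000	-0.70
MSS3	T3	chr12	35900000	133800000	-0.50
MSI-H1	T1;T2;T3	chr8	45700000	146300000	0.40
MSI-H2	T1;T2;T3	chr6	30000000	35000000	-0.60
MSI-H2	T1;T2;T3	chr6	35000000	40000000	0.40
MSI-H2	T1;T2;T3	chr6	40000000	45000000	-0.60
MSI-H2	T1;T2;T3	chr6	45000000	50000000	0.40
MSI-H2	T1;T2;T3	chr6	50000000	55000000	-0.60
MSI-H2	T1;T2;T3	chr6	55000000	60000000	0.40
MSI-H2	T1;T2;T3	chr6	60000000	65000000	-0.60
MSI-H2	T1;T2;T3	chr6	65000000	70000000	0.40
MSI-H2	T1;T2;T3	chr13	20000000	40000000	0.45
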