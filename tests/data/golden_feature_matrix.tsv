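sample	simple	complex	intra	inter	compact	sparse	deletion_length_bin1	deletion_length_bin2	deletion_length_bin3	deletion_length_bin4	deletion_length_bin5	duplication_length_bin1	duplication_length_bin2	duplication_length_bin3	duplication_length_bin4	duplication_length_bin5	insertion	reciprocal	unbalanced_translocation	LINE	chromothripsis	deletion_magnitude_bin1	deletion_magnitude_bin2	deletion_magnitude_bin3	duplication_magnitude_bin1	duplication_magnitude_bin2	duplication_magnitude_bin3	segment_size_bin1	segment_size_bin2	segment_size_bin3	segments_per_5mb_bin1	segments_per_5mb_bin2	segments_per_5mb_bin3	oscillation_chain_bin1	oscillation_chain_bin2	oscillation_chain_bin3	segments_per_arm_bin1	segments_per_arm_bin2	segments_per_arm_bin3	changepoint_bin1	changepoint_bin2	changepoint_bin3	changepoint_bin4	changepoint_bin5
S1_flat	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	1	0	0	0	3	0	0	0	0	0	0	6	0	0	0	0	0	0	0
S2_del	1	0	1	0	1	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	1	0	1	1	3	1	0	0	1	0	0	5	1	0	0	2	0	0	0
S3_dup	1	0	1	0	1	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	1	0	0	1	0	1	1	3	1	0	0	1	0	0	5	1	0	0	2	0	0	0
S4_recip	0	0	1	0	1	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	1	0	0	1	0	0	0	3	0	0	0	0	0	0	6	0	0	0	0	0	0	0
S5_tra	1	0	0	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	1	0	0	1	0	0	0	4	0	0	0	0	0	0	5	1	0	0	1	0	0	0
S6_cx	0	1	1	1	2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	1	0	0	1	0	0	0	3	0	0	0	0	0	0	6	0	0	0	0	0	0	0
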