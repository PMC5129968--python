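source	consequence
nonsynonymous SNV	missense
missense_variant	missense
stopgain	nonsense
stopgain SNV	nonsense
stop_gained	nonsense
stoploss	other
splicing	splicing
splice_acceptor_variant	splicing
splice_donor_variant	splicing
frameshift insertion	frameshift_indel
frameshift deletion	frameshift_indel
frameshift substitution	frameshift_indel
frameshift_variant	frameshift_indel
nonframeshift insertion	inframe_indel
nonframeshift deletion	inframe_indel
nonframeshift substitution	inframe_indel
inframe_insertion	inframe_indel
inframe_deletion	inframe_indel
synonymous SNV	synonymous
synonymous_variant	synonymous
unknown	other
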