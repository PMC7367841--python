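consequence	mutation_class	non_silent
missense_variant	missense	1
stop_gained	nonsense	1
stop_lost	nonsense	1
start_lost	nonsense	1
frameshift_variant	frameshift	1
inframe_insertion	in-frame indel	1
inframe_deletion	in-frame indel	1
disruptive_inframe_insertion	in-frame indel	1
disruptive_inframe_deletion	in-frame indel	1
splice_acceptor_variant	splice	1
splice_donor_variant	splice	1
splice_region_variant	splice	1
synonymous_variant	silent	0
stop_retained_variant	silent	0
start_retained_variant	silent	0
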