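# Template for a validated-degron table. One row per degron window,
# aligned on the phospho-acceptor ('0') residue (column 3 for a length-7
# CPD window). zero_protein_pos and source_ref are optional.
substrate_name	window_seq	zero_protein_pos	source_ref
EXAMPLE_SUBSTRATE	LLTPQQD	380	PMID:00000000
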