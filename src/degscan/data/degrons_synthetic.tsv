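# SYNTHETIC degron catalog: windows constructed to be consistent with the
# CPD consensus [LP][LP][TS]P..[TSDE]. These are NOT curated biological
# degrons; supply your own validated table (see degrons_template.tsv) for
# real analyses.
substrate_name	window_seq	zero_protein_pos	source_ref
SYNDEG01	LLTPADT		synthetic
SYNDEG02	LLTPADT		synthetic
SYNDEG03	LPTPQAT		synthetic
SYNDEG04	LPTPQAS		synthetic
SYNDEG05	LPTPGSS		synthetic
SYNDEG06	LPTPGSS		synthetic
SYNDEG07	LPTPVGD		synthetic
SYNDEG08	PLSPVGD		synthetic
SYNDEG09	PLSPNPD		synthetic
SYNDEG10	PLSPNPE		synthetic
SYNDEG11	PLSPKLE		synthetic
SYNDEG12	PLSPRKE		synthetic
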