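rsid	gene	risk_allele	other_allele	group
rs12785878	DHCR7	G	T	synthesis
rs12794714	CYP2R1	A	G	synthesis
rs2282679	GC	C	A	metabolism
rs6013897	CYP24A1	A	T	metabolism
rs2228570	VDR	A	G	metabolism
rs7975232	VDR	A	C	metabolism
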