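accession	name	start	end	kind	amidated
SYNP001	signal	1	20	signal	false
SYNP001	SST-pro	21	38	peptide	false
SYNP001	SST-28L	41	54	peptide	false
SYNP001	SST-14L	57	70	peptide	false
SYNP002	signal	1	20	signal	false
SYNP002	NPW-23L	21	32	peptide	true
SYNP002	NPW-CT	36	49	peptide	false
SYNP003	signal	1	20	signal	false
SYNP003	PP-L	21	56	peptide	true
SYNP003	icosapeptide-L	60	80	peptide	false
SYNP004	signal	1	20	signal	false
SYNP004	motilin-L	21	42	peptide	false
SYNP004	MLN-AP	45	58	peptide	false
SYNP005	signal	1	20	signal	false
SYNP005	SCG2-N	21	34	peptide	false
SYNP005	manserin-L	37	52	peptide	false
SYNP005	SCG2-AM	55	68	peptide	true
SYNP005	SCG2-CT	72	85	peptide	false
SYNP006	signal	1	20	signal	false
SYNP006	vasostatin-L	21	38	peptide	false
SYNP006	catestatin-L	41	59	peptide	false
SYNP006	CHGA-AM	62	75	peptide	true
SYNP006	CHGA-CT	79	92	peptide	false
SYNP007	signal	1	20	signal	false
SYNP007	VGF-N	21	40	peptide	false
SYNP007	TLQP-L	43	56	peptide	false
SYNP007	VGF-AM	59	73	peptide	true
SYNP007	VGF-CT	77	86	peptide	false
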