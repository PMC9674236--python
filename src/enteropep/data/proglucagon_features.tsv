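accession	name	start	end	kind	amidated
P01275	signal	1	20	signal	false
P01275	Glicentin	21	89	chain	false
P01275	GRPP	21	50	peptide	false
P01275	Oxyntomodulin	53	89	peptide	false
P01275	Glucagon	53	81	peptide	false
P01275	GLP-1(7-37)	98	128	peptide	false
P01275	GLP-1(7-36)	98	127	peptide	true
P01275	GLP-2	146	178	peptide	false
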