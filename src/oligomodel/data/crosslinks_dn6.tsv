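band	residue_1	residue_2	n_spectra	peptide_1	peptide_2
monomer	110	27	6	VNHVTLSQPKIVK	H2N-IQVYSR
monomer	110/113		64	VNHVTLSQPKIVKWDRDM
monomer	110/113		29	VNHVTLSQPKIVKWDR
dimer	110	113	2	VNHVTLSQPKIVK	IVKWDR
dimer	110	113	4	VNHVTLSQPKIVK	IVKWDRDM
dimer	110	27	4	VNHVTLSQPKIVK	H2N-IQVYSR
dimer	110	110	13	VNHVTLSQPKIVK	VNHVTLSQPKIVK
dimer	67	113	1	IEKVEHSDLSFSK	IVKWDRDM
dimer	110/113		40	VNHVTLSQPKIVKWDR
dimer	110/113		44	VNHVTLSQPKIVKWDRDM
dimer	67/77		1	IEKVEHSDLSFSKDWSFYLLYYTEFTPTEKDEYACR
trimer	110	113	1	VNHVTLSQPKIVKWDR	IVKWDR
trimer	110	113	1	VNHVTLSQPKIVKWDR	IVKWDRDM
trimer	110	113	2	VNHVTLSQPKIVK	IVKWDR
trimer	110	113	4	VNHVTLSQPKIVK	IVKWDRDM
trimer	110	27	6	VNHVTLSQPKIVK	H2N-IQVYSR
trimer	67	110	2	IEKVEHSDLSFSK	VNHVTLSQPKIVK
trimer	67	67	1	IEKVEHSDLSFSK	IEKVEHSDLSFSK
trimer	110	110	9	VNHVTLSQPKIVK	VNHVTLSQPKIVK
trimer	110/113		23	VNHVTLSQPKIVKWDR
trimer	110/113		24	VNHVTLSQPKIVKWDRDM
tetramer	110	113	2	VNHVTLSQPKIVK	IVKWDR
tetramer	110	113	2	VNHVTLSQPKIVK	IVKWDRDM
tetramer	110	27	2	VNHVTLSQPKIVK	H2N-IQVYSR
tetramer	67	110	2	IEKVEHSDLSFSK	VNHVTLSQPKIVK
tetramer	110	110	7	VNHVTLSQPKIVK	VNHVTLSQPKIVK
tetramer	110/113		15	VNHVTLSQPKIVKWDR
tetramer	110/113		15	VNHVTLSQPKIVKWDRDM
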