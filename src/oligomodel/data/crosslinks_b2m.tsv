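band	residue_1	residue_2	n_spectra	peptide_1	peptide_2
monomer	110	26	84	VNHVTLSQPKIVK	TPKIQVYSR
monomer	110	26	8	VNHVTLSQPKIVKWDRDM	TPKIQVYSR
monomer	110	26	3	VNHVTLSQPKIVKWDR	TPKIQVYSR
monomer	113	26	2	VNHVTLSQPKIVKWDR	TPKIQVYSR
monomer	110/113		40	VNHVTLSQPKIVKWDR
monomer	110/113		62	VNHVTLSQPKIVKWDRDM
dimer	21	26	3	H2N-IQRTPKIQVYSR	TPKIQVYSR
dimer	26	26	3	IQRTPKIQVYSR	TPKIQVYSR
dimer	26	26	20	TPKIQVYSR	TPKIQVYSR
dimer	67	26	2	IEKVEHSDLSFSK	TPKIQVYSR
dimer	67	110	1	IEKVEHSDLSFSK	VNHVTLSQPKIVK
dimer	110	26	71	VNHVTLSQPKIVK	TPKIQVYSR
dimer	110	110	6	VNHVTLSQPKIVK	VNHVTLSQPKIVK
dimer	110	113	1	VNHVTLSQPKIVK	IVKWDRDM
dimer	110	26	4	VNHVTLSQPKIVKWDRDM	TPKIQVYSR
dimer	113	26	1	IVKWDRDM	TPKIQVYSR
dimer	113	26	1	VNHVTLSQPKIVKWDR	TPKIQVYSR
dimer	113	26	3	VNHVTLSQPKIVKWDR	TPKIQVYSR
dimer	110/113		30	VNHVTLSQPKIVKWDR
dimer	110/113		41	VNHVTLSQPKIVKWDRDM
trimer	110	26	50	VNHVTLSQPKIVK	TPKIQVYSR
trimer	113	26	3	VNHVTLSQPKIVKWDR	TPKIQVYSR
trimer	110	26	2	VNHVTLSQPKIVKWDRDM	TPKIQVYSR
trimer	26	26	9	TPKIQVYSR	TPKIQVYSR
trimer	26	26	1	IQRTPKIQVYSR	TPKIQVYSR
trimer	67	110	2	IEKVEHSDLSFSK	VNHVTLSQPKIVK
trimer	67	26	2	IEKVEHSDLSFSK	TPKIQVYSR
trimer	110	110	7	VNHVTLSQPKIVK	VNHVTLSQPKIVK
trimer	110/113		16	VNHVTLSQPKIVKWDR
trimer	110/113		26	VNHVTLSQPKIVKWDRDM
tetramer	110	26	30	VNHVTLSQPKIVK	TPKIQVYSR
tetramer	26	26	8	TPKIQVYSR	TPKIQVYSR
tetramer	67	26	4	IEKVEHSDLSFSK	TPKIQVYSR
tetramer	110	110	5	VNHVTLSQPKIVK	VNHVTLSQPKIVK
tetramer	110/113		19	VNHVTLSQPKIVKWDR
tetramer	110/113		25	VNHVTLSQPKIVKWDRDM
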