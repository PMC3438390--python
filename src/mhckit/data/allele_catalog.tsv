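# mhckit allele catalog: the 75 Mafa class II DP/DQ alleles detected by full-length
# cDNA sequencing in the BPRC pedigreed cynomolgus macaque colony.
# Columns: name, locus, completeness, status, origins (comma-separated population
# tags: ind=Indonesian, mal=Malaysian, mau=Mauritian, vie=Vietnamese), accession
# (EMBL/EBI, opaque metadata), reference_animal (for novel/extension entries).
# Status: novel = not previously reported; extension = full-length sequence that
# exactly contains a previously known exon-2-only sequence; known = previously
# reported allele re-observed here. Sequences are not distributed with the
# catalog; accessions identify the deposited records.
name	locus	completeness	status	origins	accession	reference_animal
Mafa-DPA1*02:01	DPA1	full-length	extension	ind	HE573230
Mafa-DPA1*02:02	DPA1	full-length	known	ind,mau	EF208806
Mafa-DPA1*02:03	DPA1	full-length	known	ind,mau	EF208807,HM579973
Mafa-DPA1*02:06:02	DPA1	full-length	novel	ind	FR719027	Mesa
Mafa-DPA1*02:08:01	DPA1	full-length	known	ind,vie	HM580029
Mafa-DPA1*02:13:02	DPA1	full-length	novel	ind	FR719025	Tremaa
Mafa-DPA1*02:16	DPA1	full-length	known	ind	HM579972,FR719028	Amaretto
Mafa-DPA1*02:19	DPA1	full-length	novel	ind	FR719022	Donna
Mafa-DPA1*02:20	DPA1	full-length	novel	ind	FR719023	Voodoo
Mafa-DPA1*02:21	DPA1	full-length	novel	ind	FR719024	Caya
Mafa-DPA1*02:22	DPA1	full-length	novel	ind	FR719029	Kaa
Mafa-DPA1*02:23	DPA1	full-length	novel	ind	HE573229	Cornea
Mafa-DPA1*04:01	DPA1	full-length	known	ind,mau	AF208808
Mafa-DPA1*04:02	DPA1	full-length	known	ind	HM579969
Mafa-DPA1*07:02	DPA1	full-length	known	ind,mau	EF208810
Mafa-DPA1*07:04	DPA1	full-length	known	ind	HM579964,FR719026	Falcao
Mafa-DPA1*10:01	DPA1	full-length	novel	ind	FR719021	Varoa
Mafa-DPB1*01:07	DPB1	full-length	novel	ind	FR719032	Mesa
Mafa-DPB1*02:02	DPB1	full-length	known	ind,vie	HM580039
Mafa-DPB1*02:05	DPB1	full-length	novel	ind	FR719033	Mojo
Mafa-DPB1*03:01	DPB1	full-length	known	ind,vie	HM580037
Mafa-DPB1*03:03	DPB1	full-length	known	ind,mau	AM086069
Mafa-DPB1*03:04	DPB1	full-length	known	ind,vie	HM579981
Mafa-DPB1*04:01	DPB1	full-length	known	ind,mau	EF208811
Mafa-DPB1*06:01	DPB1	full-length	known	ind,vie	HM580038
Mafa-DPB1*06:03	DPB1	full-length	extension	ind	HE573231	Alfa
Mafa-DPB1*06:08	DPB1	full-length	known	ind	HM579983
Mafa-DPB1*07:01	DPB1	full-length	known	ind	HM580035
Mafa-DPB1*09:02	DPB1	full-length	known	ind,mau	EF208813,HM579980
Mafa-DPB1*10:01	DPB1	full-length	known	ind	HM579982
Mafa-DPB1*15:02	DPB1	full-length	known	ind	HM579977
Mafa-DPB1*15:03	DPB1	full-length	known	ind	AM943636
Mafa-DPB1*15:05	DPB1	full-length	extension	ind	FR719031	Voodoo
Mafa-DPB1*15:08	DPB1	full-length	novel	ind	HE753232	Dobo
Mafa-DPB1*18:01	DPB1	exon2-plus	extension	ind	HE611949	Roza
Mafa-DPB1*19:03	DPB1	exon2-plus	known	ind,mau	EF208814
Mafa-DPB1*20:01	DPB1	exon2-plus	known	ind,mau	EF208815
Mafa-DPB1*21:01	DPB1	exon2-plus	novel	ind	HE611948	Geisha
Mafa-DQA1*01:02	DQA1	full-length	extension	ind	FR719042	Pachuca
Mafa-DQA1*01:15	DQA1	full-length	extension	ind	HE573234	Joshua
Mafa-DQA1*01:06	DQA1	full-length	known	ind,mau	EF208817
Mafa-DQA1*01:07	DQA1	full-length	known	ind,mau	EF208818,HM579989
Mafa-DQA1*01:08:02	DQA1	full-length	novel	ind	FR719041	Sjerpa
Mafa-DQA1*01:13	DQA1	full-length	novel	ind	FR719037	Bamboo
Mafa-DQA1*01:14	DQA1	full-length	novel	ind	FR719038	Kaa
Mafa-DQA1*05:02	DQA1	full-length	extension	ind	FR719043	Tjatjatja
Mafa-DQA1*05:03:01	DQA1	full-length	known	ind,mau	EF208819,FR719035	Mesa
Mafa-DQA1*05:03:02	DQA1	full-length	known	ind,vie	HM579988
Mafa-DQA1*05:04	DQA1	full-length	extension	ind	FR719045	Suraya
Mafa-DQA1*05:07	DQA1	full-length	novel	ind	FR719034	Caya
Mafa-DQA1*05:08	DQA1	full-length	novel	ind	FR719039	Domino
Mafa-DQA1*05:09	DQA1	full-length	novel	ind	FR719040	Varoa
Mafa-DQA1*23:01	DQA1	full-length	extension	ind	FR719044	Mojo
Mafa-DQA1*24:02:01	DQA1	exon2-plus	known	ind	AM943643
Mafa-DQA1*24:02:03	DQA1	full-length	novel	ind	HE611950	Geisha
Mafa-DQA1*24:03	DQA1	exon2-plus	known	ind	EF208820,HE573233
Mafa-DQA1*24:06	DQA1	full-length	novel	ind	HE573235	Xueso
Mafa-DQA1*26:01:02	DQA1	full-length	novel	ind	FR719036
Mafa-DQB1*06:01:02	DQB1	full-length	known	ind,mau	EF442017
Mafa-DQB1*06:07:01	DQB1	full-length	known	ind	HM579998
Mafa-DQB1*06:08	DQB1	full-length	known	ind,mau	EF208822
Mafa-DQB1*06:11	DQB1	full-length	known	ind,mau	EF208823,HM153008
Mafa-DQB1*06:15	DQB1	full-length	extension	ind	FR719054	Colorado
Mafa-DQB1*06:17	DQB1	full-length	extension	ind	FR719048	Bamboo
Mafa-DQB1*06:23	DQB1	full-length	extension	ind	HE573237	Kaa
Mafa-DQB1*16:01	DQB1	full-length	extension	ind	FR719046	Mesa
Mafa-DQB1*17:02:01	DQB1	full-length	known	ind,vie	FR719051
Mafa-DQB1*17:02:02	DQB1	full-length	novel	ind	FR719049
Mafa-DQB1*17:04	DQB1	full-length	extension	ind	FR719053
Mafa-DQB1*17:05	DQB1	full-length	extension	ind	FR719052
Mafa-DQB1*17:06:02	DQB1	full-length	extension	ind	FR719050
Mafa-DQB1*18:01:01	DQB1	full-length	known	ind,mau	EF208825
Mafa-DQB1*18:04	DQB1	full-length	extension	ind	FR719047
Mafa-DQB1*18:06	DQB1	full-length	extension	ind	HE573238
Mafa-DQB1*18:08	DQB1	full-length	known	ind,mal	EZ933325,HE573236
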