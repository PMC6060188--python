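lesion_id	patient_id	sex	age	histology	who_grade	verification	days_before_pet	ki67_percent
1	P01	F	58	oligodendroglioma	II	SB	4	3
2	P02	M	38	oligodendroglioma	II	SB	19	3
3	P03	M	56	diffuse astrocytoma	II	SB	13	4
4	P04	M	36	oligodendroglioma	II	SB	14	<1
5	P05	M	39	oligodendroglioma	II	EB	42	N/A
6	P06	F	32	diffuse astrocytoma	II	EB	61	4
7	P07	M	45	anaplastic astrocytoma	III	EB	31	40
8	P08	F	50	glioblastoma	IV	SB	7	12
9	P09	M	70	glioblastoma	IV	SB	15	40
10	P10	F	72	glioblastoma	IV	SB	27	30
11	P10	F	72	glioblastoma	IV	SB	27	30
12	P11	M	58	glioblastoma	IV	EB	3	N/A
13	P12	F	36	glioblastoma	IV	EB	13	N/A
14	P12	F	36	glioblastoma	IV	EB	13	N/A
15	P13	F	58	glioblastoma	IV	EB	14	10
16	P14	F	65	glioblastoma	IV	EB	16	35
17	P15	M	67	glioblastoma	IV	EB	13	8
18	P16	F	60	glioblastoma	IV	EB	18	N/A
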