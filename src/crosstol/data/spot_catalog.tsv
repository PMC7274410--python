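spot_id	accession	phytozome_id	description	category
1	P26413	Glyma17g08020	Heat shock protein 70	response-to-heat
2	P08824	Glyma12g08310	Chaperonin subunit alpha 60 kDa	protein-refolding
3	P26413	Glyma17g08020	Heat shock protein 70	response-to-heat
4	A8IKE5	Glyma02g04320	Alanine aminotransferase 2	metabolism
5	B0M1A4	Glyma06g02040	Catalase	redox
6	P02581	Glyma05g09290	Actin	protein-refolding
7	O82560	Glyma14g39420	Glutamine synthetase	metabolism
8	D4N5G3	Glyma11g34230	Rubisco activase	photosynthesis
9	Q6RIB7	Glyma19g37520	Enolase	photosynthesis
10	Q6RIB8	Other	5-hydroxytryptamine receptor 4	other
11	A0A762	Glyma10g28890	Calreticulin	protein-refolding
12	C6ZJZ0	Glyma18g150000	Serine hydroxymethyltransferase 5	metabolism
13	O23963	Glyma05g02670	Translation elongation factor	metabolism
14	Q9ZT38	Glyma04g41990	Alcohol dehydrogenase	redox
15	E5RPJ6	Glyma05g27260	Pyruvate dehydrogenase	metabolism
16	I1JJ05	Glyma02g45190	Oxygen-evolving enhancer protein 2	photosynthesis
17	Q2IOH4	Glyma06g18110	Glyceraldehyde 3-phosphate dehydrogenase	photosynthesis
18	O81278	Glyma05g01010	NAD dependent malate dehydrogenase	metabolism
19	Q43758	Glyma11g15680	Ascorbate peroxidase	redox
20	Q38IW8	Glyma15g04290	Triosephosphate isomerase	metabolism
21	Q93XE6	Glyma20g38560	Chalcone flavone isomerase 1A	metabolism
22	O22443	Glyma09g02590	Peroxidase	metabolism
23	O22443	Glyma09g02591	Peroxidase	metabolism
24	Q9XJ23	Glyma12g01000	Acid phosphatase	metabolism
25	Q39831	Glyma05g25810	Chlorophyll A/B-binding protein	photosynthesis
26	C6SZ56	Glyma19g42890	Superoxide dismutase	redox
27	Q39818	Glyma12g01580	Heat shock protein 22 (mitochondrial)	response-to-heat
28	Q39818	Glyma12g01580	Heat shock protein 22 (mitochondrial)	response-to-heat
29	B3GV28	Glyma07g09240	Peroxiredoxin	redox
30	Q39832	Glyma19g06370	Ribulose bisphosphate carboxylase small chain 1	photosynthesis
31	P04795	Glyma14g06910	Heat shock protein 17.6 kDa class 1	response-to-heat
32	P04795	Glyma14g06910	Heat shock protein 17.6 kDa class 1	response-to-heat
33	Q9SWA8	Glyma12g04701	Glycine-rich RNA binding protein	metabolism
34	B4X941	VIGUN	17.7 kDa class 1 heat shock protein	response-to-heat
35	P10743	Glyma08g21410	Stem 31 kDa glycoprotein precursor	other
36	Q9ZTZ2	Glyma17g16620	Late embryogenesis abundant protein	other
37	Q8GV24	Glyma07g3710	Nucleoside diphosphate kinase	metabolism
38	Q6RUF6	Glyma14g01470	Fructose bisphosphate aldolase	photosynthesis
39	O82561	Glyma14g39421	Glutamine synthetase	metabolism
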