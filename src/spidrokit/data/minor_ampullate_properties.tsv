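species	source_rank	diameter_um	modulus_gpa	strength_mpa	extensibility	toughness_j_cm3	gpg_percent
Latrodectus_hesperus	1	1.12	3.9	245.4	0.57	66.7	0.07
Latrodectus_geometricus	1	1.09	2.6	174.4	0.54	43.6	3.48
Steatoda_grossa	1	1.07	2.1	251.3	0.74	57.3	12.79
Nephila_clavipes	1	2.5	3.0	346	0.30	50	0
Nephila_clavipes	2	2.5		960	0.25		0
Nephila_inaurata	1	1.8	11.2	1500	0.46	300
Argiope_trifasciata	1	0.69	8.9	751.5	0.44	150
Argiope_trifasciata	2	1.8	10	1040	0.45	240
Argiope_argentata	1	1.1	10.6	923	0.33	137
Araneus_diadematus	1				0.29		0
Araneus_gemmoides	1	2.0		1400	0.22
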