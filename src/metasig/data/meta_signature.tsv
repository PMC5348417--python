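mirna	direction	p_value	corrected_p	n_studies
hsa-miR-200c-3p	up	9.40E-09	1.94E-05	7
hsa-miR-200a-3p	up	9.09E-07	1.88E-03	7
hsa-miR-141-3p	up	4.28E-05	8.83E-02	6
hsa-miR-200b-3p	up	1.02E-04	2.10E-01	6
hsa-miR-93-5p	up	1.85E-04	3.82E-01	6
hsa-miR-20a-5p	up	1.90E-04	3.92E-01	5
hsa-miR-145-5p	down	3.37E-04	6.96E-01	7
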