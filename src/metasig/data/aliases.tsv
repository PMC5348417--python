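reported_name	canonical_name
hsa-miR-200c	hsa-miR-200c-3p
hsa-mir-200c	hsa-miR-200c-3p
hsa-miR-200a	hsa-miR-200a-3p
hsa-mir-200a	hsa-miR-200a-3p
hsa-miR-200b	hsa-miR-200b-3p
hsa-mir-200b	hsa-miR-200b-3p
hsa-miR-141	hsa-miR-141-3p
hsa-mir-141	hsa-miR-141-3p
hsa-miR-93	hsa-miR-93-5p
hsa-mir-93	hsa-miR-93-5p
hsa-miR-20a	hsa-miR-20a-5p
hsa-mir-20a	hsa-miR-20a-5p
hsa-miR-145	hsa-miR-145-5p
hsa-mir-145	hsa-miR-145-5p
hsa-miR-126	hsa-miR-126-3p
hsa-miR-29a	hsa-miR-29a-3p
hsa-miR-200c*	hsa-miR-200c-5p
hsa-miR-141*	hsa-miR-141-5p
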