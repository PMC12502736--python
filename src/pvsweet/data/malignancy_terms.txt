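# Indication terms treated as malignancy-related (one per line, matched
# case-insensitively as substrings of the reported indication PT).
# Edit to taste; these defaults cover the haematological and solid-tumour
# indications that dominate Sweet-syndrome comorbidity.
acute myeloid leukaemia
acute lymphocytic leukaemia
chronic myeloid leukaemia
chronic lymphocytic leukaemia
leukaemia
myelodysplastic syndrome
myelofibrosis
plasma cell myeloma
multiple myeloma
lymphoma
hodgkin
neoplasm
cancer
carcinoma
melanoma
sarcoma
tumour
tumor
polycythaemia vera
essential thrombocythaemia
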