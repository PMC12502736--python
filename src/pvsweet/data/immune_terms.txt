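# Indication terms treated as immune-related (one per line, matched
# case-insensitively as substrings of the reported indication PT).
crohn's disease
crohns disease
ulcerative colitis
inflammatory bowel disease
rheumatoid arthritis
psoriasis
psoriatic arthropathy
systemic lupus erythematosus
lupus
ankylosing spondylitis
behcet
sjogren
vasculitis
sarcoidosis
multiple sclerosis
autoimmune
immune thrombocytopenia
dermatomyositis
polymyalgia rheumatica
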