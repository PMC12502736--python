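# standardized name	ATC level-1	ATC level-2
azathioprine	L	L04
adalimumab	L	L04
infliximab	L	L04
vedolizumab	L	L04
tocilizumab	L	L04
azacitidine	L	L01
decitabine	L	L01
venetoclax	L	L01
bortezomib	L	L01
ruxolitinib	L	L01
lenalidomide	L	L04
hydroxycarbamide	L	L01
cytarabine	L	L01
ibrutinib	L	L01
filgrastim	L	L03
pegfilgrastim	L	L03
etanercept	L	L04
rituximab	L	L01
sulfamethoxazole/trimethoprim	J	J01
levofloxacin	J	J01
ofloxacin	J	J01
ciprofloxacin	J	J01
amoxicillin	J	J01
azithromycin	J	J01
linezolid	J	J01
valaciclovir	J	J05
hydroxychloroquine	P	P01
mesalazine	A	A07
sulfasalazine	A	A07
omeprazole	A	A02
metformin	A	A10
paracetamol	N	N02
diclofenac	M	M01
celecoxib	M	M01
gabapentin	N	N03
methotrexate	L	L04
hydralazine	C	C02
amlodipine	C	C08
furosemide	C	C03
atorvastatin	C	C10
lisinopril	C	C09
ethinylestradiol/levonorgestrel	G	G03
levothyroxine	H	H03
prednisone	H	H02
prednisolone	H	H02
salbutamol	R	R03
sertraline	N	N06
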