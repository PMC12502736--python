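# raw name	standardized name
humira	adalimumab
adalimumab-atto	adalimumab
remicade	infliximab
imuran	azathioprine
azasan	azathioprine
vidaza	azacitidine
dacogen	decitabine
neupogen	filgrastim
neulasta	pegfilgrastim
bactrim	sulfamethoxazole/trimethoprim
septra	sulfamethoxazole/trimethoprim
trimethoprim/sulfamethoxazole	sulfamethoxazole/trimethoprim
co-trimoxazole	sulfamethoxazole/trimethoprim
velcade	bortezomib
venclexta	venetoclax
hydrea	hydroxycarbamide
hydroxyurea	hydroxycarbamide
jakafi	ruxolitinib
asacol	mesalazine
mesalamine	mesalazine
valtrex	valaciclovir
valacyclovir	valaciclovir
plaquenil	hydroxychloroquine
levaquin	levofloxacin
zithromax	azithromycin
amoxil	amoxicillin
zyvox	linezolid
acetaminophen	paracetamol
tylenol	paracetamol
voltaren	diclofenac
entyvio	vedolizumab
apresoline	hydralazine
revlimid	lenalidomide
enbrel	etanercept
rituxan	rituximab
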