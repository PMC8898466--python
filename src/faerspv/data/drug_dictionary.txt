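# Drug dictionary: one [label] block per drug of interest, one name pattern
# per line (generic and brand names; matching is case-insensitive,
# word-boundary substring on drugname and active-ingredient fields).

[tigecycline]
tigecycline
tygacil

[vancomycin]
vancomycin
vancocin
firvanq
vancoled

[linezolid]
linezolid
zyvox

[daptomycin]
daptomycin
cubicin

[meropenem]
meropenem
merrem

[imipenem_cilastatin]
imipenem
cilastatin
primaxin

[cefoperazone]
cefoperazone
cefobid
sulperazon
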