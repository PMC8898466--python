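# Event dictionary: one [group] block per event group, one MedDRA preferred
# term per line (case-insensitive exact PT match).  The umbrella group
# 'coagulation_dysfunction' must contain every PT of the named subgroups; it
# may add further coagulation-related PTs that belong to no subgroup.

[thrombocytopenia]
Thrombocytopenia
Platelet count decreased

[hypofibrinogenaemia]
Hypofibrinogenaemia
Blood fibrinogen decreased
Afibrinogenaemia

[coagulopathy]
Coagulopathy
Disseminated intravascular coagulation
Coagulation test abnormal

[aptt_prolonged]
Activated partial thromboplastin time prolonged

[inr_increased]
International normalised ratio increased

[pt_prolonged]
Prothrombin time prolonged

[coagulation_dysfunction]
Thrombocytopenia
Platelet count decreased
Hypofibrinogenaemia
Blood fibrinogen decreased
Afibrinogenaemia
Coagulopathy
Disseminated intravascular coagulation
Coagulation test abnormal
Activated partial thromboplastin time prolonged
International normalised ratio increased
Prothrombin time prolonged
Blood fibrinogen abnormal
Prothrombin time abnormal
Activated partial thromboplastin time abnormal
International normalised ratio abnormal
Hypoprothrombinaemia
Haemorrhagic diathesis
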