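cohort_id,low,high,obesity
AMS_OA,167,79,307
STABILO,60,37,62
NEXA,33,23,44
CBT,94,16,112
VIDEX,67,58,52
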