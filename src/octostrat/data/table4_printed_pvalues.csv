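variable,group_a,group_b,p
sex,low,high,<0.001
sex,low,obesity,0.03
sex,high,obesity,<0.001
age,low,high,<0.001
age,low,obesity,<0.001
age,high,obesity,0.55
kl,low,high,0.02
kl,low,obesity,0.44
kl,high,obesity,<0.001
surgery,low,high,0.01
surgery,low,obesity,0.80
surgery,high,obesity,0.02
comorbidity,low,high,0.02
comorbidity,low,obesity,<0.001
comorbidity,high,obesity,<0.001
pain,low,high,<0.001
pain,low,obesity,0.31
pain,high,obesity,<0.001
function,low,high,<0.001
function,low,obesity,<0.001
function,high,obesity,<0.001
bmi,low,high,<0.01
bmi,low,obesity,<0.001
bmi,high,obesity,<0.001
strength_iso,low,high,<0.001
strength_iso,low,obesity,0.03
strength_iso,high,obesity,<0.001
strength_cst,low,high,<0.001
strength_cst,low,obesity,0.15
strength_cst,high,obesity,<0.001
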