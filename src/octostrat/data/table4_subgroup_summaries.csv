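variable,kind,subgroup,category,mean,sd,n,count
sex,categorical,low,female,,,,310
sex,categorical,low,male,,,,111
sex,categorical,high,female,,,,88
sex,categorical,high,male,,,,125
sex,categorical,obesity,female,,,,388
sex,categorical,obesity,male,,,,189
age,continuous,low,,65.2,8.4,421,
age,continuous,high,,62.3,8.6,213,
age,continuous,obesity,,62.7,8.3,577,
kl,categorical,low,0/1,,,,95
kl,categorical,low,2,,,,131
kl,categorical,low,3,,,,92
kl,categorical,low,4,,,,83
kl,categorical,high,0/1,,,,72
kl,categorical,high,2,,,,64
kl,categorical,high,3,,,,48
kl,categorical,high,4,,,,42
kl,categorical,obesity,0/1,,,,128
kl,categorical,obesity,2,,,,145
kl,categorical,obesity,3,,,,137
kl,categorical,obesity,4,,,,132
surgery,categorical,low,yes,,,,51
surgery,categorical,low,no,,,,76
surgery,categorical,high,yes,,,,24
surgery,categorical,high,no,,,,14
surgery,categorical,obesity,yes,,,,65
surgery,categorical,obesity,no,,,,90
comorbidity,categorical,low,0,,,,142
comorbidity,categorical,low,1,,,,61
comorbidity,categorical,low,2,,,,13
comorbidity,categorical,low,3+,,,,14
comorbidity,categorical,high,0,,,,97
comorbidity,categorical,high,1,,,,28
comorbidity,categorical,high,2,,,,8
comorbidity,categorical,high,3+,,,,3
comorbidity,categorical,obesity,0,,,,151
comorbidity,categorical,obesity,1,,,,105
comorbidity,categorical,obesity,2,,,,52
comorbidity,categorical,obesity,3+,,,,41
pain,continuous,low,,5.6,2.0,421,
pain,continuous,high,,4.7,2.2,213,
pain,continuous,obesity,,5.8,2.1,577,
function,continuous,low,,43.6,17.3,421,
function,continuous,high,,30.6,18.2,213,
function,continuous,obesity,,48.7,18.6,577,
bmi,continuous,low,,26.4,2.5,421,
bmi,continuous,high,,25.8,2.4,213,
bmi,continuous,obesity,,35.5,5.0,577,
strength_iso,continuous,low,,0.71,0.31,294,
strength_iso,continuous,high,,1.62,0.32,174,
strength_iso,continuous,obesity,,0.78,0.48,421,
strength_cst,continuous,low,,8.5,2.3,127,
strength_cst,continuous,high,,13.2,1.2,39,
strength_cst,continuous,obesity,,9.0,2.7,156,
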