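cohort_id,n,n_exercise,strength_instrument,pain_scale,has_surgery,has_comorbidity,has_followup
AMS_OA,553,0,isokinetic,nrs_0_10,0,1,0
STABILO,159,159,isokinetic,nrs_0_10,0,0,1
NEXA,100,100,cst30,vas_0_100,1,0,1
CBT,222,148,cst30,vas_0_100,1,0,1
VIDEX,177,177,isokinetic,nrs_0_10,0,1,1
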