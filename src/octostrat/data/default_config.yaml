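rules:
  bmi_obesity_cutoff: 30.0
  isokinetic_cutoff: 1.2
  cst30_cutoff: 12.0
  max_proportion_deviation: 10.0
  alpha: 0.05
  large_es_min: 0.6
  medium_es_min: 0.3
  medium_es_max: 0.7
  small_es_max: 0.4
  majority_min: 67.0
  half_min: 33.0
  half_max: 67.0
  minority_max: 33.0
  pain_mic_percent: 0.15
  pain_mic_absolute: 1.0
  womac_mic_percent: 0.12
  isokinetic_mic_percent: 0.3
  cst30_mic_absolute: 2.0
generator:
  cohorts:
  - cohort_id: AMS_OA
    n: 553
    strength_instrument: isokinetic
    pain_scale: nrs_0_10
    exercise_fraction: 0.0
    has_surgery: false
    has_comorbidity: true
    mixture:
      low: 0.30198915009041594
      high: 0.14285714285714285
      obesity: 0.5551537070524413
  - cohort_id: STABILO
    n: 159
    strength_instrument: isokinetic
    pain_scale: nrs_0_10
    exercise_fraction: 1.0
    has_surgery: false
    has_comorbidity: false
    mixture:
      low: 0.37735849056603776
      high: 0.23270440251572327
      obesity: 0.389937106918239
  - cohort_id: NEXA
    n: 100
    strength_instrument: cst30
    pain_scale: vas_0_100
    exercise_fraction: 1.0
    has_surgery: true
    has_comorbidity: false
    mixture:
      low: 0.33
      high: 0.23
      obesity: 0.44
  - cohort_id: CBT
    n: 222
    strength_instrument: cst30
    pain_scale: vas_0_100
    exercise_fraction: 0.6666666666666666
    has_surgery: true
    has_comorbidity: false
    mixture:
      low: 0.42342342342342343
      high: 0.07207207207207207
      obesity: 0.5045045045045045
  - cohort_id: VIDEX
    n: 177
    strength_instrument: isokinetic
    pain_scale: nrs_0_10
    exercise_fraction: 1.0
    has_surgery: false
    has_comorbidity: true
    mixture:
      low: 0.3785310734463277
      high: 0.327683615819209
      obesity: 0.2937853107344633
  subgroups:
    low:
      age:
        mean: 65.2
        sd: 8.4
        lower: 18.0
        upper: 100.0
      female_p: 0.7363420427553444
      bmi:
        mean: 26.4
        sd: 2.5
        lower: 15.0
        upper: 30.0
      strength_iso:
        mean: 0.71
        sd: 0.31
        lower: 0.0
        upper: 1.2
      strength_cst:
        mean: 8.5
        sd: 2.3
        lower: 0
        upper: 11
      pain:
        mean: 5.6
        sd: 2.0
        lower: 0.0
        upper: 10.0
      womac:
        mean: 43.6
        sd: 17.3
        lower: 0.0
        upper: 100.0
      kl_probs:
        0/1: 0.23690773067331672
        '2': 0.3266832917705736
        '3': 0.22942643391521197
        '4': 0.20698254364089774
      surgery_p: 0.4015748031496063
      comorbidity_probs:
        '0': 0.6173913043478261
        '1': 0.26521739130434785
        '2': 0.05652173913043478
        3+: 0.06086956521739131
    high:
      age:
        mean: 62.3
        sd: 8.6
        lower: 18.0
        upper: 100.0
      female_p: 0.4131455399061033
      bmi:
        mean: 25.8
        sd: 2.4
        lower: 15.0
        upper: 30.0
      strength_iso:
        mean: 1.62
        sd: 0.32
        lower: 1.2
      strength_cst:
        mean: 13.2
        sd: 1.2
        lower: 12
        upper: 30
      pain:
        mean: 4.7
        sd: 2.2
        lower: 0.0
        upper: 10.0
      womac:
        mean: 30.6
        sd: 18.2
        lower: 0.0
        upper: 100.0
      kl_probs:
        0/1: 0.3185840707964602
        '2': 0.2831858407079646
        '3': 0.21238938053097345
        '4': 0.18584070796460178
      surgery_p: 0.631578947368421
      comorbidity_probs:
        '0': 0.7132352941176471
        '1': 0.20588235294117646
        '2': 0.058823529411764705
        3+: 0.022058823529411766
    obesity:
      age:
        mean: 62.7
        sd: 8.3
        lower: 18.0
        upper: 100.0
      female_p: 0.6724436741767764
      bmi:
        mean: 35.5
        sd: 5.0
        lower: 30.0
        upper: 70.0
      strength_iso:
        mean: 0.78
        sd: 0.48
        lower: 0.0
      strength_cst:
        mean: 9.0
        sd: 2.7
        lower: 0
        upper: 30
      pain:
        mean: 5.8
        sd: 2.1
        lower: 0.0
        upper: 10.0
      womac:
        mean: 48.7
        sd: 18.6
        lower: 0.0
        upper: 100.0
      kl_probs:
        0/1: 0.23616236162361623
        '2': 0.26752767527675275
        '3': 0.25276752767527677
        '4': 0.24354243542435425
      surgery_p: 0.41935483870967744
      comorbidity_probs:
        '0': 0.4326647564469914
        '1': 0.3008595988538682
        '2': 0.1489971346704871
        3+: 0.1174785100286533
  effects:
    noise_ratio: 0.5
    delta:
      low/pain: 1.05
      obesity/pain: 1.1
      high/pain: 0.82
      low/function: 0.79
      obesity/function: 0.78
      high/function: 0.49
      low/strength_isokinetic: 0.74
      obesity/strength_isokinetic: 0.27
      high/strength_isokinetic: 0.19
      low/strength_cst30: 0.73
      obesity/strength_cst30: 0.6
      high/strength_cst30: 0.32
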