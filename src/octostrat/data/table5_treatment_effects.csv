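subgroup,outcome,instrument,effect_size,mic_rate
low,pain,,1.05,70
low,function,,0.79,79
low,strength,isokinetic,0.74,49
low,strength,cst30,0.73,31
obesity,pain,,1.10,72
obesity,function,,0.78,76
obesity,strength,isokinetic,0.27,32
obesity,strength,cst30,0.60,28
high,pain,,0.82,66
high,function,,0.49,76
high,strength,isokinetic,0.19,7
high,strength,cst30,0.32,9
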