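condition,cost_event_fatal,cost_event_nonfatal,cost_subsequent,utility_decrement
t2dm,,494.5,494.5,0.220
ihd,,3558.4,1175.2,0.090
mi,2295.6,6861.8,1129.8,0.055
heart_failure,3968.4,3968.4,1391.1,0.108
stroke,5786.8,4196.9,793.4,0.164
revascularisation,,4943.1,316.3,0.059
amputation,13664.2,13664.2,788.7,0.280
blindness,,1791.7,758.9,0.074
renal_failure,30599.2,30599.2,30599.2,0.263
cvd_death,3724.3,,,
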