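category,label,centre,unit_rate,quantity,multiplicity,extra,lump_sum
delivery,Design of materials,shared,44,8,2,0,
delivery,Practitioner folders,shared,8.2,1,170,0,
delivery,Patient folders,shared,5.8,1,513,0,
delivery,Hand-outs,shared,,,,,446
delivery,Consultation meeting with health professionals,shared,44,2,1,5,
delivery,Focus group meeting consultants,shared,121,3,3,15,
delivery,Focus group meeting nurses,shared,44,3,3,15,
delivery,Preparatory meetings consultants,Cambridge,121,3,200,0,
delivery,Preparatory meetings doctors,Cambridge,121,1.5,450,0,
delivery,Preparatory meetings practice nurses,Cambridge,30,1.5,200,0,
delivery,Structured education sessions,Leicester,44,6,12,324.6,
extra_consultations,GP visits (10 min x 3/year x 3 years),Cambridge,,,,,121091
extra_consultations,Nurse visits (10 min x 3/year x 3 years),Cambridge,,,,,19637
extra_consultations,Clinic initial and extra visits,Leicester,,,,,28534
extra_consultations,Clinic follow-up and annual review visits,Leicester,,,,,20748
extra_treatments,Extra prescriptions (SU / ACE inhibitors / statins),Cambridge,262.5,1,452,0,
extra_treatments,Extra prescriptions (SU / ACE inhibitors / statins),Leicester,262.5,1,61,0,
extra_treatments,Glucometers and strips (95% of participants),shared,,,,,4406
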