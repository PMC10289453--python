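scenario,country,block,key,value
STUDY_OBSERVED,KE,summary,n_facilities,9
STUDY_OBSERVED,KE,summary,package_total,1109066
STUDY_OBSERVED,KE,summary,per_facility,123229
STUDY_OBSERVED,KE,summary,per_birth,48.13
STUDY_OBSERVED,KE,summary,control_per_birth,15.22
STUDY_OBSERVED,KE,input_type,PERSONNEL_PROGRAM,416669
STUDY_OBSERVED,KE,input_type,PERSONNEL_CONSULTANT,280183
STUDY_OBSERVED,KE,input_type,PERSONNEL_FACILITY,254985
STUDY_OBSERVED,KE,input_type,CONSUMABLES,32694
STUDY_OBSERVED,KE,input_type,CAPITAL,13070
STUDY_OBSERVED,KE,input_type,OFFICE_CONF_SPACE,13008
STUDY_OBSERVED,KE,input_type,TRAVEL,99231
STUDY_OBSERVED,KE,component,GENERAL,122091
STUDY_OBSERVED,KE,component,DS,56183
STUDY_OBSERVED,KE,component,MSCC,30834
STUDY_OBSERVED,KE,component,PRONTO,627478
STUDY_OBSERVED,KE,component,QI,272479
STUDY_OBSERVED,UG,summary,n_facilities,4
STUDY_OBSERVED,UG,summary,package_total,737257
STUDY_OBSERVED,UG,summary,per_facility,184314
STUDY_OBSERVED,UG,summary,per_birth,17.19
STUDY_OBSERVED,UG,summary,control_per_birth,6.13
STUDY_OBSERVED,UG,input_type,PERSONNEL_PROGRAM,274898
STUDY_OBSERVED,UG,input_type,PERSONNEL_CONSULTANT,241319
STUDY_OBSERVED,UG,input_type,PERSONNEL_FACILITY,72236
STUDY_OBSERVED,UG,input_type,CONSUMABLES,31441
STUDY_OBSERVED,UG,input_type,CAPITAL,12214
STUDY_OBSERVED,UG,input_type,OFFICE_CONF_SPACE,10776
STUDY_OBSERVED,UG,input_type,TRAVEL,96053
STUDY_OBSERVED,UG,component,GENERAL,106480
STUDY_OBSERVED,UG,component,DS,45034
STUDY_OBSERVED,UG,component,MSCC,24011
STUDY_OBSERVED,UG,component,PRONTO,285198
STUDY_OBSERVED,UG,component,QI,256534
MOH_MODEL,KE,summary,n_facilities,17
MOH_MODEL,KE,summary,package_total,858445
MOH_MODEL,KE,summary,per_facility,50497
MOH_MODEL,KE,summary,per_birth,23.91
MOH_MODEL,KE,summary,per_birth_phase3,16.36
MOH_MODEL,KE,summary,control_per_birth,6.78
MOH_MODEL,KE,input_type,PERSONNEL_PROGRAM,158214
MOH_MODEL,KE,input_type,PERSONNEL_CONSULTANT,107631
MOH_MODEL,KE,input_type,PERSONNEL_FACILITY,490717
MOH_MODEL,KE,input_type,CONSUMABLES,30622
MOH_MODEL,KE,input_type,CAPITAL,21146
MOH_MODEL,KE,input_type,OFFICE_CONF_SPACE,21319
MOH_MODEL,KE,input_type,TRAVEL,28779
MOH_MODEL,KE,component,GENERAL,202569
MOH_MODEL,KE,component,DS,88283
MOH_MODEL,KE,component,MSCC,40931
MOH_MODEL,KE,component,PRONTO,379223
MOH_MODEL,KE,component,QI,147421
MOH_MODEL,UG,summary,n_facilities,6
MOH_MODEL,UG,summary,package_total,281224
MOH_MODEL,UG,summary,per_facility,46871
MOH_MODEL,UG,summary,per_birth,5.47
MOH_MODEL,UG,summary,per_birth_phase3,3.47
MOH_MODEL,UG,summary,control_per_birth,1.59
MOH_MODEL,UG,input_type,PERSONNEL_PROGRAM,46758
MOH_MODEL,UG,input_type,PERSONNEL_CONSULTANT,93593
MOH_MODEL,UG,input_type,PERSONNEL_FACILITY,65570
MOH_MODEL,UG,input_type,CONSUMABLES,26489
MOH_MODEL,UG,input_type,CAPITAL,13170
MOH_MODEL,UG,input_type,OFFICE_CONF_SPACE,5467
MOH_MODEL,UG,input_type,TRAVEL,30176
MOH_MODEL,UG,component,GENERAL,76001
MOH_MODEL,UG,component,DS,26753
MOH_MODEL,UG,component,MSCC,18567
MOH_MODEL,UG,component,PRONTO,123302
MOH_MODEL,UG,component,QI,36599
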