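row,base_assumption,alt_assumption,ke_base,ke_alt,ke_pct_printed,ug_base,ug_alt,ug_pct_printed
nm_travelling,NMs hired from and embedded within facilities (one NM per facility),NMs travel to facilities,23.91,24.92,4,5.47,6.02,10
adaptation_2x,Minimal adjustments to package of interventions,Moderate adjustments (twice the effort of base case),23.91,25.82,8,5.47,6.68,22
maintenance_high,Maintenance: PRONTO 1 day/mo; QICs every 6 months,Maintenance: PRONTO 2 days/mo; QICs every 3 months,23.91,27.49,15,5.47,5.91,8
facility_mix_ug,Six high-volume facilities in Uganda,Observed Uganda prices in mix of high- and low-volume facilities,,,,5.47,8.11,49
facility_mix_ke,Mix of high- and low-volume facilities in Kenya (17),Observed Kenya prices in only high-volume facilities,23.91,11.90,-50,,,
exclude_facility_worker_time,Includes time spent by facility-based workers in intervention activities,Excludes health worker time,23.91,10.76,-55,5.47,4.48,-18
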