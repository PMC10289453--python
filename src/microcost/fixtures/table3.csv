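country,section,item,unit_price,units,unit_label
KE,program_based,County or regional/district MNCH coordinator,2181,3.5,months
KE,program_based,Sub-county or associate MNCH coordinator,1211,10,months
KE,program_based,Senior obstetrician,3656,4.5,months
KE,program_based,Senior pediatrician,3656,4.5,months
KE,program_based,Statistician/biostatistician,1203,7,months
KE,program_based,Data quality/mSCC specialist,870,42,months
KE,program_based,DHIS/HMIS specialist,1203,5.5,months
KE,program_based,PRONTO/QI specialist,1286,65,months
KE,facility_based,Principal medical officer,2505,30,months
KE,facility_based,Maternity/newborn unit in-charge,1534,48,months
KE,facility_based,PRONTO Nurse Mentor,1211,85,months
KE,facility_based,Registered nurse or midwife,840,204,months
KE,facility_based,Health records clerk,472,72,months
KE,office_supplies,PRONTO Manuals - Professional printing,38,20,units
KE,office_supplies,PRONTO Manuals - Local printing,6,341,units
KE,office_supplies,"DS, mSCC, and QI training packets",2,403,units
KE,office_supplies,mSCC paper and printing,18,372,per-100-checklists
KE,clinic_goods,Single-use PRONTO supplies,214,40,mentor-years
KE,capital,Computer,998,4,units
KE,capital,Office desk and chair,115,4,units
KE,capital,Projector,232,1,units
KE,capital,Neonatal resuscitation mannequin,85,32,units
KE,capital,Bag-valve masks (neonatal/preterm),46,20,units
KE,office_conf,Hotel conference room,628,6,days
KE,office_conf,Food/beverage - offsite meetings,18,128,person-days
KE,office_conf,Value of office space for specialists,105,132,months
KE,travel,Airfare: US to in-country,2000,3,return trips
KE,travel,Airfare: Within East Africa,215,21,return trips
KE,travel,Hotel accommodation and food,65,102,nights
KE,travel,Petrol/vehicle expenses - local travel,9,1280,return trips
UG,program_based,County or regional/district MNCH coordinator,807,3.5,months
UG,program_based,Sub-county or associate MNCH coordinator,718,10,months
UG,program_based,Senior obstetrician,576,4,months
UG,program_based,Senior pediatrician,576,4,months
UG,program_based,Statistician/biostatistician,658,6.5,months
UG,program_based,Data quality/mSCC specialist,386,25,months
UG,program_based,DHIS/HMIS specialist,658,5.5,months
UG,program_based,PRONTO/QI specialist,386,31,months
UG,facility_based,Principal medical officer,389,23,months
UG,facility_based,Maternity/newborn unit in-charge,389,33,months
UG,facility_based,PRONTO Nurse Mentor,386,35,months
UG,facility_based,Registered nurse or midwife,210,158,months
UG,facility_based,Health records clerk,121,34,months
UG,office_supplies,PRONTO Manuals - Professional printing,38,10,units
UG,office_supplies,PRONTO Manuals - Local printing,5,212,units
UG,office_supplies,"DS, mSCC, and QI training packets",2,197,units
UG,office_supplies,mSCC paper and printing,15,507,per-100-checklists
UG,clinic_goods,Single-use PRONTO supplies,198,18,mentor-years
UG,capital,Computer,821,2,units
UG,capital,Office desk and chair,91,2,units
UG,capital,Projector,137,1,units
UG,capital,Neonatal resuscitation mannequin,85,18,units
UG,capital,Bag-valve masks (neonatal/preterm),26,7,units
UG,office_conf,Hotel conference room,343,6,days
UG,office_conf,Food/beverage - offsite meetings,15,116,person-days
UG,office_conf,Value of office space for specialists,28,72,months
UG,travel,Airfare: US to in-country,1850,3,return trips
UG,travel,Airfare: Within East Africa,310,18,return trips
UG,travel,Hotel accommodation and food,55,51,nights
UG,travel,Petrol/vehicle expenses - local travel,11,537,return trips
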