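prefix,category,system
I50,heart failure,PQI
I110,heart failure,PQI
E10,diabetes,PQI
E11,diabetes,PQI
E13,diabetes,PQI
E14,diabetes,PQI
I10,hypertension,PQI
I119,hypertension,PQI
J45,asthma,PQI
J46,asthma,PQI
J40,chronic obstructive pulmonary disease,PQI
J41,chronic obstructive pulmonary disease,PQI
J42,chronic obstructive pulmonary disease,PQI
J43,chronic obstructive pulmonary disease,PQI
J44,chronic obstructive pulmonary disease,PQI
J47,chronic obstructive pulmonary disease,PQI
J13,bacterial pneumonia,PQI
J14,bacterial pneumonia,PQI
J15,bacterial pneumonia,PQI
J18,bacterial pneumonia,PQI
N390,urinary tract infection,PQI
N10,urinary tract infection,PQI
N12,urinary tract infection,PQI
E86,dehydration,PQI
I20,angina without procedure,PQI
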