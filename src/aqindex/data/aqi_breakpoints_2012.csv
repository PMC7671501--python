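pollutant,conc_lo,conc_hi,index_lo,index_hi,category,decimals
pm25,0.0,12.0,0,50,Good,1
pm25,12.1,35.4,51,100,Moderate,1
pm25,35.5,55.4,101,150,Unhealthy for Sensitive Groups,1
pm25,55.5,150.4,151,200,Unhealthy,1
pm25,150.5,250.4,201,300,Very Unhealthy,1
pm25,250.5,350.4,301,400,Hazardous,1
pm25,350.5,500.4,401,500,Hazardous,1
o3,0,59,0,50,Good,0
o3,60,75,51,100,Moderate,0
o3,76,95,101,150,Unhealthy for Sensitive Groups,0
o3,96,115,151,200,Unhealthy,0
o3,116,374,201,300,Very Unhealthy,0
no2,0,53,0,50,Good,0
no2,54,100,51,100,Moderate,0
no2,101,360,101,150,Unhealthy for Sensitive Groups,0
no2,361,649,151,200,Unhealthy,0
no2,650,1249,201,300,Very Unhealthy,0
no2,1250,1649,301,400,Hazardous,0
no2,1650,2049,401,500,Hazardous,0
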