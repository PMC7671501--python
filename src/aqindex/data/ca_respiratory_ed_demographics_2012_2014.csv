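region,variable,category,count
San Francisco Bay Area,age_group,18-40,139227
San Francisco Bay Area,age_group,41-64,108697
San Francisco Bay Area,age_group,65+,52304
San Francisco Bay Area,sex,female,178167
San Francisco Bay Area,sex,male,122061
San Francisco Bay Area,race,white,107786
San Francisco Bay Area,race,hispanic,84217
San Francisco Bay Area,race,black,63211
San Francisco Bay Area,race,asian_pacific_islander,22600
San Francisco Bay Area,race,native_american,1670
San Francisco Bay Area,race,other,20744
San Joaquin Valley,age_group,18-40,122612
San Joaquin Valley,age_group,41-64,78940
San Joaquin Valley,age_group,65+,32163
San Joaquin Valley,sex,female,143170
San Joaquin Valley,sex,male,90545
San Joaquin Valley,race,white,96773
San Joaquin Valley,race,hispanic,94809
San Joaquin Valley,race,black,24440
San Joaquin Valley,race,asian_pacific_islander,4378
San Joaquin Valley,race,native_american,650
San Joaquin Valley,race,other,12665
Southern California,age_group,18-40,405300
Southern California,age_group,41-64,291971
Southern California,age_group,65+,141951
Southern California,sex,female,507866
Southern California,sex,male,331356
Southern California,race,white,316726
Southern California,race,hispanic,311663
Southern California,race,black,134765
Southern California,race,asian_pacific_islander,31642
Southern California,race,native_american,1684
Southern California,race,other,42742
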