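region,county
Southern California,Ventura
Southern California,Santa Barbara
Southern California,San Luis Obispo
Southern California,San Diego
Southern California,San Bernardino
Southern California,Riverside
Southern California,Orange
Southern California,Los Angeles
Southern California,Imperial
San Joaquin Valley,Tulare
San Joaquin Valley,Stanislaus
San Joaquin Valley,San Joaquin
San Joaquin Valley,Merced
San Joaquin Valley,Madera
San Joaquin Valley,Kings
San Joaquin Valley,Kern
San Joaquin Valley,Fresno
San Francisco Bay Area,Sonoma
San Francisco Bay Area,Solano
San Francisco Bay Area,Santa Clara
San Francisco Bay Area,San Mateo
San Francisco Bay Area,Napa
San Francisco Bay Area,Monterey
San Francisco Bay Area,Contra Costa
San Francisco Bay Area,Alameda
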