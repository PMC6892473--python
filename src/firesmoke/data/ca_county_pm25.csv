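# County-level mean daily PM2.5 (ug/m3), California 2007-2013, from the
# paired CMAQ runs. San Francisco contains no 12-km cell centroid and has
# no data (empty fields).
county,all_sources_mean,all_sources_sd,fire_mean,fire_sd
Alameda,8.50,5.90,0.84,3.76
Alpine,3.13,7.63,1.57,7.55
Amador,6.21,7.15,1.87,6.78
Butte,6.61,13.34,2.63,13.14
Calaveras,5.46,7.06,1.88,6.79
Colusa,5.17,8.99,1.97,8.72
Contra Costa,11.05,8.29,0.98,4.13
Del Norte,4.42,12.02,2.74,11.88
El Dorado,5.37,7.90,2.23,7.70
Fresno,5.23,4.42,1.10,3.73
Glenn,5.25,9.46,2.04,9.21
Humboldt,4.63,11.22,2.61,11.09
Imperial,3.46,1.61,0.26,0.64
Inyo,2.28,2.19,0.49,1.43
Kern,4.81,3.29,0.76,2.41
Kings,7.52,6.63,0.93,3.48
Lake,4.37,10.94,2.12,10.83
Lassen,3.30,6.88,1.61,6.78
Los Angeles,8.41,4.09,0.57,1.68
Madera,5.45,4.84,1.31,4.39
Marin,4.97,5.55,0.84,3.80
Mariposa,4.47,8.33,2.08,8.24
Mendocino,4.31,11.45,2.26,11.35
Merced,7.40,6.21,1.10,4.36
Modoc,2.74,4.36,1.25,4.20
Mono,2.32,3.52,0.82,3.32
Monterey,3.99,4.06,0.81,3.49
Napa,5.39,7.85,1.53,7.43
Nevada,5.64,10.48,2.25,10.30
Orange,12.09,6.10,0.51,1.57
Placer,6.99,10.87,2.41,10.67
Plumas,4.50,11.04,2.43,10.93
Riverside,4.28,2.18,0.34,0.95
Sacramento,11.83,9.68,1.53,6.50
San Benito,4.12,3.92,0.74,3.12
San Bernardino,3.42,2.12,0.36,0.96
San Diego,5.80,2.84,0.40,1.22
San Francisco,,,,
San Joaquin,9.72,7.78,1.16,5.07
San Luis Obispo,4.42,3.47,0.63,2.18
San Mateo,6.23,6.22,0.70,3.17
Santa Barbara,3.83,2.87,0.64,2.25
Santa Clara,7.28,5.37,0.86,3.84
Santa Cruz,6.43,5.38,0.86,3.62
Shasta,4.52,9.12,2.24,9.00
Sierra,3.84,8.48,1.83,8.36
Siskiyou,4.24,9.93,2.63,9.87
Solano,8.26,7.41,1.25,5.62
Sonoma,5.37,8.68,1.53,8.32
Stanislaus,7.52,6.57,1.17,5.11
Sutter,9.03,9.51,1.79,7.68
Tehama,5.17,12.97,2.68,12.88
Trinity,5.10,19.25,3.57,19.20
Tulare,5.11,3.63,1.07,3.06
Tuolumne,4.46,9.68,2.26,9.65
Ventura,4.74,2.95,0.56,1.77
Yolo,7.30,8.68,1.69,7.76
Yuba,7.77,9.38,2.03,8.70
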