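# SYNTHETIC baseline demographics for the bundled scenario (not registry data).
# Per country/sex/age-cohort: crude lung cancer incidence rate per 100,000 in
# the first registry year (2000), resident population in 2000, and a constant
# annual population growth rate (%/yr) emulating cohort aging in a smooth
# national projection. Rates are realistic order-of-magnitude values for
# western-European populations around 2000 (male rates several-fold female
# rates, both strongly age-increasing); the absolute level is rescaled at run
# time by the scenario calibration, so only the age/sex profile matters here.
country,sex,age_group,base_rate_per_100k,population_2000,pop_growth_pct
France,M,40-44,20,2100000,0.1
France,M,45-49,45,2050000,0.1
France,M,50-54,90,2000000,0.2
France,M,55-59,140,1600000,1.5
France,M,60-64,200,1300000,1.8
France,M,65-69,280,1200000,1.8
France,M,70-74,340,1000000,1.5
France,M,75-79,360,800000,1.5
France,M,80-84,330,420000,2.0
France,M,85+,260,280000,2.5
France,F,40-44,8,2100000,0.1
France,F,45-49,14,2050000,0.1
France,F,50-54,22,2000000,0.2
France,F,55-59,30,1600000,1.5
France,F,60-64,35,1300000,1.8
France,F,65-69,40,1300000,1.8
France,F,70-74,45,1200000,1.5
France,F,75-79,50,1100000,1.5
France,F,80-84,50,680000,2.0
France,F,85+,45,620000,2.5
Germany,M,40-44,20,2940000,0.1
Germany,M,45-49,45,2870000,0.1
Germany,M,50-54,90,2800000,0.2
Germany,M,55-59,140,2240000,1.5
Germany,M,60-64,200,1820000,1.8
Germany,M,65-69,280,1680000,1.8
Germany,M,70-74,340,1400000,1.5
Germany,M,75-79,360,1120000,1.5
Germany,M,80-84,330,590000,2.0
Germany,M,85+,260,390000,2.5
Germany,F,40-44,8,2940000,0.1
Germany,F,45-49,14,2870000,0.1
Germany,F,50-54,22,2800000,0.2
Germany,F,55-59,30,2240000,1.5
Germany,F,60-64,35,1820000,1.8
Germany,F,65-69,40,1820000,1.8
Germany,F,70-74,45,1680000,1.5
Germany,F,75-79,50,1540000,1.5
Germany,F,80-84,50,950000,2.0
Germany,F,85+,45,870000,2.5
Italy,M,40-44,20,2040000,0.1
Italy,M,45-49,45,1990000,0.1
Italy,M,50-54,90,1940000,0.2
Italy,M,55-59,140,1550000,1.5
Italy,M,60-64,200,1260000,1.8
Italy,M,65-69,280,1160000,1.8
Italy,M,70-74,340,970000,1.5
Italy,M,75-79,360,780000,1.5
Italy,M,80-84,330,410000,2.0
Italy,M,85+,260,270000,2.5
Italy,F,40-44,8,2040000,0.1
Italy,F,45-49,14,1990000,0.1
Italy,F,50-54,22,1940000,0.2
Italy,F,55-59,30,1550000,1.5
Italy,F,60-64,35,1260000,1.8
Italy,F,65-69,40,1260000,1.8
Italy,F,70-74,45,1160000,1.5
Italy,F,75-79,50,1070000,1.5
Italy,F,80-84,50,660000,2.0
Italy,F,85+,45,600000,2.5
Spain,M,40-44,20,1430000,0.1
Spain,M,45-49,45,1390000,0.1
Spain,M,50-54,90,1360000,0.2
Spain,M,55-59,140,1090000,1.5
Spain,M,60-64,200,880000,1.8
Spain,M,65-69,280,820000,1.8
Spain,M,70-74,340,680000,1.5
Spain,M,75-79,360,540000,1.5
Spain,M,80-84,330,290000,2.0
Spain,M,85+,260,190000,2.5
Spain,F,40-44,8,1430000,0.1
Spain,F,45-49,14,1390000,0.1
Spain,F,50-54,22,1360000,0.2
Spain,F,55-59,30,1090000,1.5
Spain,F,60-64,35,880000,1.8
Spain,F,65-69,40,880000,1.8
Spain,F,70-74,45,820000,1.5
Spain,F,75-79,50,750000,1.5
Spain,F,80-84,50,460000,2.0
Spain,F,85+,45,420000,2.5
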