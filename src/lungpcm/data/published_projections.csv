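# Published patient-count projections for advanced NSCLC second/third line of
# therapy (LOT), by country and year: deterministic value plus probabilistic
# (PSA) mean and 95% CI, all rounded to the nearest 100 patients. The 2016
# deterministic values serve as calibration anchors for the bundled synthetic
# scenario; the 2020 values are recorded for reference.
country,lot,year,deterministic,psa_mean,ci_low,ci_high
France,second,2016,11600,11700,10500,12800
France,second,2020,13900,13900,12500,15400
France,third,2016,3500,3500,3200,3800
France,third,2020,4200,4200,3800,4500
Germany,second,2016,15100,15200,13600,16700
Germany,second,2020,16200,16200,14600,17900
Germany,third,2016,4900,4900,4500,5400
Germany,third,2020,5200,5300,4800,5700
Italy,second,2016,13500,13600,11900,15600
Italy,second,2020,15100,15600,13500,18200
Italy,third,2016,2500,2500,2200,2800
Italy,third,2020,2600,2700,2400,3100
Spain,second,2016,9400,9600,8400,11100
Spain,second,2020,11000,11800,9600,14700
Spain,third,2016,2100,2200,1900,2400
Spain,third,2020,2500,2600,2200,3300
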