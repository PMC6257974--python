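# Published annual percent change (APC) estimates for the last joinpoint segment
# of lung cancer incidence rates, by country, sex and age cohort (registry-based
# analyses, data years 2000 through the country's last available year).
# significant = 1 marks estimates reported significant at p < 0.05.
country,sex,age_group,apc_pct,significant
France,M,40-44,-4.8,1
France,M,45-49,-4.1,1
France,M,50-54,-0.8,0
France,M,55-59,0.8,0
France,M,60-64,1.4,1
France,M,65-69,1.5,1
France,M,70-74,0.6,0
France,M,75-79,0.6,0
France,M,80-84,0.7,0
France,M,85+,4.1,0
France,F,40-44,-1.8,0
France,F,45-49,1.2,0
France,F,50-54,8.2,1
France,F,55-59,8.6,1
France,F,60-64,8.5,1
France,F,65-69,7.9,1
France,F,70-74,6.0,1
France,F,75-79,4.1,1
France,F,80-84,5.6,0
France,F,85+,9.3,1
Germany,M,40-44,-6.4,0
Germany,M,45-49,-5.1,0
Germany,M,50-54,-6.8,0
Germany,M,55-59,-1.3,0
Germany,M,60-64,-0.4,0
Germany,M,65-69,-0.6,0
Germany,M,70-74,-2.7,0
Germany,M,75-79,-4.8,0
Germany,M,80-84,-0.6,0
Germany,M,85+,-0.1,0
Germany,F,40-44,-2.8,0
Germany,F,45-49,-2.7,0
Germany,F,50-54,-1.9,0
Germany,F,55-59,2.6,0
Germany,F,60-64,6.4,0
Germany,F,65-69,6.1,0
Germany,F,70-74,2.1,0
Germany,F,75-79,-2.2,0
Germany,F,80-84,1.9,0
Germany,F,85+,3.2,0
Italy,M,40-44,-7.3,1
Italy,M,45-49,-5.0,1
Italy,M,50-54,-4.6,1
Italy,M,55-59,-3.5,1
Italy,M,60-64,-0.9,0
Italy,M,65-69,-2.4,1
Italy,M,70-74,-3.2,1
Italy,M,75-79,-1.4,1
Italy,M,80-84,-3.8,0
Italy,M,85+,2.2,1
Italy,F,40-44,-1.9,0
Italy,F,45-49,3.7,1
Italy,F,50-54,7.6,1
Italy,F,55-59,8.2,1
Italy,F,60-64,3.1,1
Italy,F,65-69,2.4,1
Italy,F,70-74,1.2,0
Italy,F,75-79,1.9,1
Italy,F,80-84,3.8,1
Italy,F,85+,6.4,1
Spain,M,40-44,-4.5,1
Spain,M,45-49,-2.3,0
Spain,M,50-54,-2.0,0
Spain,M,55-59,1.9,0
Spain,M,60-64,-0.1,0
Spain,M,65-69,0.8,0
Spain,M,70-74,-0.5,0
Spain,M,75-79,-0.2,0
Spain,M,80-84,-1.5,0
Spain,M,85+,-7.6,0
Spain,F,40-44,1.9,0
Spain,F,45-49,9.5,0
Spain,F,50-54,14.9,1
Spain,F,55-59,4.5,0
Spain,F,60-64,10.2,1
Spain,F,65-69,4.3,0
Spain,F,70-74,7.2,1
Spain,F,75-79,-1.5,0
Spain,F,80-84,-1.0,0
Spain,F,85+,-1.8,1
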