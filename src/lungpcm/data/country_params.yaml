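# Published country-level parameter estimates for the advanced-NSCLC patient
# count model: lung cancer morphology, NSCLC histology mix, stage at diagnosis,
# five-year distant recurrence by early stage, median overall survival of
# previously treated advanced disease, systemic-treatment eligibility, and
# proportions receiving each line of therapy (LOT) by histology.
# All values are percentages except median_os_months.
France:
  pct_nsclc: 83.1
  pct_squamous: 38.3
  pct_nonsquamous: 61.7
  stage_dist:
    I: 7.5
    II: 7.9
    III: 25.2
    IV: 52.9
    unknown: 6.5
  pct_IIIb_of_III: 49.6
  recurrence_5yr:
    I: 25.8
    II: 45.8
    IIIA: 44.8
  median_os_months:
    squamous: 6.0
    nonsquamous: 9.4
  pct_bsc: 11.7
  pct_eligible: 88.3
  lot_rates:
    squamous:
      first: 77.9
      second: 28.6
      third: 10.4
    nonsquamous:
      first: 89.5
      second: 46.8
      third: 12.9
Germany:
  pct_nsclc: 81.2
  pct_squamous: 35.9
  pct_nonsquamous: 64.1
  stage_dist:
    I: 13.7
    II: 8.3
    III: 33.4
    IV: 41.3
    unknown: 3.3
  pct_IIIb_of_III: 60.8
  recurrence_5yr:
    I: 25.8
    II: 45.8
    IIIA: 44.8
  median_os_months:
    squamous: 6.0
    nonsquamous: 9.4
  pct_bsc: 11.7
  pct_eligible: 88.3
  lot_rates:
    squamous:
      first: 89.2
      second: 37.8
      third: 9.5
    nonsquamous:
      first: 93.8
      second: 52.3
      third: 18.5
Italy:
  pct_nsclc: 84.8
  pct_squamous: 32.2
  pct_nonsquamous: 67.8
  stage_dist:
    I: 10.0
    II: 5.9
    III: 23.3
    IV: 53.5
    unknown: 7.3
  pct_IIIb_of_III: 63.1
  recurrence_5yr:
    I: 25.8
    II: 45.8
    IIIA: 44.8
  median_os_months:
    squamous: 6.0
    nonsquamous: 9.4
  pct_bsc: 11.7
  pct_eligible: 88.3
  lot_rates:
    squamous:
      first: 90.0
      second: 42.2
      third: 10.0
    nonsquamous:
      first: 92.3
      second: 57.7
      third: 8.7
Spain:
  pct_nsclc: 86.6
  pct_squamous: 40.5
  pct_nonsquamous: 59.5
  stage_dist:
    I: 7.4
    II: 6.2
    III: 33.4
    IV: 48.5
    unknown: 4.5
  pct_IIIb_of_III: 68.3
  recurrence_5yr:
    I: 25.8
    II: 45.8
    IIIA: 44.8
  median_os_months:
    squamous: 6.0
    nonsquamous: 9.4
  pct_bsc: 11.7
  pct_eligible: 88.3
  lot_rates:
    squamous:
      first: 97.5
      second: 39.2
      third: 2.5
    nonsquamous:
      first: 99.1
      second: 54.3
      third: 16.4
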