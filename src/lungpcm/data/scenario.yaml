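# Bundled scenario settings: registry coverage (incidence data years used for
# trend fitting differ by country) and published external validation figures.
registry_years:
  France: [2000, 2012]
  Germany: [2000, 2012]
  Italy: [2000, 2009]
  Spain: [2000, 2007]
# Observation noise (coefficient of variation) applied to synthetic registry
# rates in the bundled scenario.
noise_cv: 0.02
# Published 2015 French lung cancer incidence: the national surveillance
# institute's projection vs the count model's forecast (persons).
validation:
  france_2015_incidence_surveillance: 45222
  france_2015_incidence_model: 45456
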