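# Published constants for the Portuguese bread market, 2016 baseline year.
per_capita_bread_g_day: 100.3
population: 10300000
prepackaged_sold_t_yr: 40040
imported_t_yr: 21764
traditional_fraction_of_national: 0.45
bakery_compliance_fraction: 0.76
per_capita_salt_g_day: 7.4
bread_share_of_salt: 0.182
days_per_year: 365.25
# Reported market total; the intake-derived total is ~0.3% higher.
total_t_yr: 376218
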