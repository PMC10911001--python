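# Small demonstration region: 16 tracts, 20 stations, two years of days.
[region]
region_size_km = 48.0
n_tracts_side = 4
n_days = 730
n_stations = 20
seed = 5

[pipeline]
reference_source = "station"
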