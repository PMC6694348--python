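energy_keV,yield
55.79,0.015
63.2,0.0036
71.642,0.00154
112.9498,0.062
136.7245,0.00047
208.3662,0.1036
249.6742,0.002012
321.3159,0.00216
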