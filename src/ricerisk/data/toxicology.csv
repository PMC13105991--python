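element,rfd_table1,rfd_mc,sf,limit_mg_kg,lod_mg_kg,lod_alt_mg_kg,ptmi
Pb,0.0014,,0.0085,0.2,0.0040,0.0040,
Cd,0.0005,0.001,6.1,0.2,0.0030,0.0030,25
iAs,0.0003,,1.5,0.2,0.0040,0.0500,
Hg,0.0003,,,0.02,0.0050,0.0005,
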