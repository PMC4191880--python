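subject,area_lost_um2,volume_lost_fl,hb_lost_pg,area_pct,volume_pct,hb_pct
1,23.3,16.5,3.8,-13.7,-14.3,-9.9
2,20.4,15.4,2.7,-11.9,-13.1,-7.3
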