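# Published symbiotic-performance means (four replicates each) for pea and
# lentil plants inoculated with Rlv UPM791 wild type, the gntR (RLV_1934A)
# insertion mutant UPM1418, and the complemented strain UPM1419. Units:
# shoot dry weight mg/plant, N fixed mg/plant.
strain	pea_shoot_dry_weight	pea_n_fixed	lentil_shoot_dry_weight	lentil_n_fixed
Control	162.4	2.22	113.8	1.42
UPM791	482.9	21.96	283.9	7.22
UPM1418	347.8	15.74	235.4	6.39
UPM1419	327.9	15.31	209.5	5.87
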