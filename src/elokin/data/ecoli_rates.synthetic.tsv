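# SYNTHETIC in-vivo-like transition rates for the 12-state elongation cycle.
# Magnitudes chosen once for physiological plausibility (overall elongation
# ~10-25 aa/s, missense error frequency ~1e-3); units s^-1, kappa_* uM^-1 s^-1.
# rsd column is a nominal placeholder.
rate	value	rsd	pathway
kappa_on	100.0	0.1	2-1-2
omega_off	20000.0	0.1	2-1-2
omega_rec	10000.0	0.1	2-1-2
omega_21	500.0	0.1	2-1-2
omega_23	2000.0	0.1	2-1-2
omega_con	1000.0	0.1	2-1-2
omega_40	30.0	0.1	2-1-2
omega_45	500.0	0.1	2-1-2
omega_76	10000.0	0.1	2-1-2
omega_78	8.0	0.1	2-1-2
omega_90	400.0	0.1	2-1-2
omega_9_10	10.0	0.1	2-1-2
omega_pro	30.0	0.1	2-1-2
kappa_on	100.0	0.1	2-3-2
omega_off	20000.0	0.1	2-3-2
omega_rec	10000.0	0.1	2-3-2
omega_21	500.0	0.1	2-3-2
omega_23	2000.0	0.1	2-3-2
omega_con	1000.0	0.1	2-3-2
omega_40	30.0	0.1	2-3-2
omega_45	500.0	0.1	2-3-2
omega_76	10000.0	0.1	2-3-2
omega_78	8.0	0.1	2-3-2
omega_90	400.0	0.1	2-3-2
omega_9_10	10.0	0.1	2-3-2
omega_pro	27.0	0.1	2-3-2
kappa_ass	10.0	0.1	both
omega_dis	0.05	0.1	both
omega_re	15.0	0.1	both
omega_elo_0.7	12.2	0.1	both
omega_elo_1.07	15.1	0.1	both
omega_elo_1.6	18.0	0.1	both
omega_elo_2.5	22.0	0.1	both
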