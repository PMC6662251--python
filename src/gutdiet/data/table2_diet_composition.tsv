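species	season	prey	frequency_of_occurrence	relative_abundance
Coreius guichenoti	spring	Limnoperna lacustris	82.86	77.44
Coreius guichenoti	spring	Hydropsychidae	3.81	0.76
Coreius guichenoti	spring	Perlidae	12.86	2.42
Coreius guichenoti	spring	Anax	1.43	0.08
Coreius guichenoti	spring	Tubificidae	3.33	0.02
Coreius guichenoti	spring	Macrobrachium	1.9	0.52
Coreius guichenoti	spring	Sinopotamidae	7.14	10.04
Coreius guichenoti	spring	Bellamya	3.33	2.04
Coreius guichenoti	spring	Detritus	17.14	6.68
Coreius guichenoti	autumn	Limnoperna lacustris	65.31	72.41
Coreius guichenoti	autumn	Perlidae	2.55	0.31
Coreius guichenoti	autumn	Anax	0.51	0.05
Coreius guichenoti	autumn	Tubificidae	1.02	0.01
Coreius guichenoti	autumn	Sinopotamidae	17.35	17.14
Coreius guichenoti	autumn	Fishes	0.51	0.47
Coreius guichenoti	autumn	Detritus	12.76	9.61
Coreius heterodon	spring	Limnoperna lacustris	85.71	80.89
Coreius heterodon	spring	Hydropsychidae	6.12	2.84
Coreius heterodon	spring	Perlidae	4.08	8.56
Coreius heterodon	spring	Tubificidae	6.12	0.02
Coreius heterodon	spring	Bellamya	8.16	0.91
Coreius heterodon	spring	Sphaerium	2.04	0.02
Coreius heterodon	spring	Detritus	10.2	6.75
Coreius heterodon	autumn	Limnoperna lacustris	86.54	98.38
Coreius heterodon	autumn	Detritus	3.85	1.62
Rhinogobio ventralis	spring	Limnoperna lacustris	91.86	97.97
Rhinogobio ventralis	spring	Perlidae	4.65	1.72
Rhinogobio ventralis	spring	Tubificidae	4.65	0.01
Rhinogobio ventralis	spring	Sphaerium	5.81	0.29
Rhinogobio ventralis	spring	Chironomidae	1.16	0.01
Rhinogobio ventralis	spring	Detritus	1.16	0.01
Rhinogobio ventralis	autumn	Limnoperna lacustris	100	99.37
Rhinogobio ventralis	autumn	Sphaerium	2.94	0.64
Rhinogobio cylindricus	spring	Limnoperna lacustris	89.66	89.68
Rhinogobio cylindricus	spring	Hydropsychidae	24.14	9.52
Rhinogobio cylindricus	spring	Gammarus	3.45	0.02
Rhinogobio cylindricus	spring	Ephemeroptera	1.72	0.04
Rhinogobio cylindricus	spring	Gerridae	1.72	0.01
Rhinogobio cylindricus	spring	Detritus	8.62	0.73
Rhinogobio cylindricus	autumn	Limnoperna lacustris	31.25	56.18
Rhinogobio cylindricus	autumn	Hydropsychidae	95.31	4.12
Rhinogobio cylindricus	autumn	Tubificidae	31.25	0.12
Rhinogobio cylindricus	autumn	Detritus	42.19	39.59
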