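species	season	n	mean_standard_length_mm	se_standard_length_mm	min_standard_length_mm	max_standard_length_mm
Coreius guichenoti	spring	260	175.3	41.0	106	297
Coreius guichenoti	autumn	226	195.4	29.3	124	334
Coreius heterodon	spring	65	207.3	22.3	168	264
Coreius heterodon	autumn	96	238.5	27.0	175	320
Rhinogobio ventralis	spring	105	156.2	31.7	97	225
Rhinogobio ventralis	autumn	50	174.2	12.6	136	201
Rhinogobio cylindricus	spring	61	185.0	21.7	143	252
Rhinogobio cylindricus	autumn	73	191.8	22.6	154	292
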