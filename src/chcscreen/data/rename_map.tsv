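# Gene-name harmonization map: HSAL70 -> HSAL71 odorant-receptor annotations.
# All entries are relative to the old (HSAL70) vocabulary and are applied
# atomically in one pass, never sequentially. swap = 1 marks the single
# exchanged pair (applied as two simultaneous rows).
old_name	new_name	swap
HsOr307.1	HsOr307	0
HsOr307.2	HsOr380	0
HsOr131.1	HsOr131	0
HsOr131.2	HsOr381	0
HsOr93.1	HsOr93	0
HsOr93.2	HsOr382	0
HsOr89.1	HsOr89	0
HsOr89.2	HsOr383	0
HsOr77.1	HsOr77	0
HsOr77.2	HsOr384	0
HsOr257.1	HsOr257	0
HsOr257.2	HsOr258	0
HsOr257.3	HsOr259	0
HsOr257.4	HsOr385	0
HsOr258	HsOr386	0
HsOr182.1	HsOr182	0
HsOr182.2	HsOr387	0
HsOr211.1	HsOr211	0
HsOr211.2	HsOr388	0
LOC105187615	HsOr303	0
HsOr378	HsOr379	1
HsOr379	HsOr378	1
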