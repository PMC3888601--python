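# RYR2 mutation hotspots (Yano-style definitions).
gene	label	start	end	group
RYR2	N-terminal hotspot	77	466	hotspots
RYR2	Central hotspot	2246	2534	hotspots
RYR2	Channel hotspot	3778	4959	hotspots
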