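# Curated skin-aging co-metabolism catalog: ten host processes and the
# bacterial gene models assigned to each.  One model belongs to exactly
# one module; hutH (urocanic acid production) is housed under UV-B induced
# immune suppression, the remaining hut-operon genes under histidine
# conversion.
pathway	module_id	model_name
UV-B induced immune suppression	uvb_immune_suppression	hutH
Histidine conversion	histidine_conversion	hutU
Histidine conversion	histidine_conversion	hutL
Histidine conversion	histidine_conversion	hutI
Histidine conversion	histidine_conversion	hutG
Protein glycation	protein_glycation	frk
Protein glycation	protein_glycation	cscK
Pigmentation	pigmentation	tyr
Ceramide metabolism	ceramide_metabolism	cerN
Ceramide metabolism	ceramide_metabolism	sphR
Fatty acid metabolism	fatty_acid_metabolism	fabG
Fatty acid metabolism	fatty_acid_metabolism	fabH
Fatty acid metabolism	fatty_acid_metabolism	fabI
Fatty acid metabolism	fatty_acid_metabolism	fadB
Fatty acid metabolism	fatty_acid_metabolism	fadI
Fatty acid metabolism	fatty_acid_metabolism	fadJ
Lipoteichoic acid signaling	lta_biosynthesis	ltaS
Lipoteichoic acid signaling	lta_biosynthesis	tagA
Lipoteichoic acid signaling	lta_biosynthesis	tagB
Porphyrin synthesis	porphyrin_synthesis	deoR
Porphyrin synthesis	porphyrin_synthesis	hemA
Porphyrin synthesis	porphyrin_synthesis	hemB
Porphyrin synthesis	porphyrin_synthesis	hemL
Proteolysis	proteolysis	lasA
Proteolysis	proteolysis	lasB
Proteolysis	proteolysis	sspA
Proteolysis	proteolysis	sspB
Proteolysis	proteolysis	sspC
Oxygen radical production and scavenging	radical_scavenging	katA
Oxygen radical production and scavenging	radical_scavenging	katG
Oxygen radical production and scavenging	radical_scavenging	sodA
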