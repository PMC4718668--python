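region_id	full_name	area_group	x	y
Cg1	cingulate cortex	prefrontal cortex	1.0	9.5
PrL	prelimbic cortex	prefrontal cortex	2.0	9.0
IL	infralimbic cortex	prefrontal cortex	3.0	9.5
VLO	ventrolateral/orbital cortex	prefrontal cortex	4.0	9.0
M1	primary motor cortex	sensorimotor cortex	6.0	9.5
M2	secondary motor cortex	sensorimotor cortex	7.0	9.0
S1	primary sensory cortex	sensorimotor cortex	8.0	9.5
cM1	caudal primary motor cortex	sensorimotor cortex	6.5	8.3
AI	agranular insular cortex	sensorimotor cortex	7.5	8.3
cAI	caudal agranular insular cortex	sensorimotor cortex	8.5	8.8
dmCPu	dorsomedial caudate putamen	striatum	4.5	6.5
dlCPu	dorsolateral caudate putamen	striatum	6.0	6.5
vmCPu	ventromedial caudate putamen	striatum	4.5	5.3
vlCPu	ventrolateral caudate putamen	striatum	6.0	5.3
NAcC	nucleus accumbens core	striatum	3.2	4.6
NAcSh	nucleus accumbens shell	striatum	2.2	5.2
CA1	hippocampal field CA1	hippocampus/septum	0.8	6.8
CA2	hippocampal field CA2	hippocampus/septum	0.4	5.8
CA3	hippocampal field CA3	hippocampus/septum	0.8	4.8
DG	dentate gyrus	hippocampus/septum	1.6	5.8
MS	medial septum	hippocampus/septum	1.2	3.8
LS	lateral septum	hippocampus/septum	2.0	3.2
BNST	bed nucleus of the stria terminalis	amygdala/hypothalamus	4.0	2.2
PVN	paraventricular nucleus of the hypothalamus	amygdala/hypothalamus	5.2	2.6
BLA	basolateral amygdala	amygdala/hypothalamus	6.4	1.8
CeA	central nucleus of the amygdala	amygdala/hypothalamus	7.4	2.4
MeA	medial nucleus of the amygdala	amygdala/hypothalamus	8.2	1.6
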