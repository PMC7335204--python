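short_name	full_name	source_atlas	hemisphere
mPFC	medial prefrontal cortex	Destrieux	bilateral
dlPFC	dorsolateral prefrontal cortex	Brodmann	bilateral
vlPFC	ventrolateral prefrontal cortex	Destrieux	bilateral
pACC	perigenual anterior cingulate cortex	Destrieux	bilateral
sACC	subgenual anterior cingulate cortex	Destrieux	bilateral
aMCC	anterior middle cingulate cortex	Destrieux	bilateral
pMCC	posterior middle cingulate cortex	Destrieux	bilateral
PCC	posterior cingulate cortex	Destrieux	bilateral
insula anterior	anterior insula	Larsson et al. 2012	bilateral
insula mid	middle insula	Larsson et al. 2012	bilateral
insula posterior	posterior insula	Larsson et al. 2012	bilateral
amygdala	amygdala	AAL	bilateral
parahippo	parahippocampal gyrus	Destrieux	bilateral
hippocampus	hippocampus	Destrieux	bilateral
SII	secondary somatosensory cortex	Destrieux	bilateral
SI	primary somatosensory cortex	Destrieux	bilateral
LTC	lateral temporal cortex	Destrieux	bilateral
IPL	inferior parietal lobule	Destrieux	bilateral
precuneus	precuneus	Destrieux	bilateral
Angular	Angular gyrus	Destrieux	bilateral
putamen	putamen	AAL	bilateral
thalamus	thalamus	AAL	bilateral
PAG	peri-aqueductal gray	sphere 6mm around MNI 0,-28,-8	midline
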