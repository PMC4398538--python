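[
 {
  "name": "superior frontal",
  "hemisphere": "lh",
  "lobe": "prefrontal"
 },
 {
  "name": "caudal middle frontal",
  "hemisphere": "lh",
  "lobe": "prefrontal"
 },
 {
  "name": "rostral middle frontal",
  "hemisphere": "lh",
  "lobe": "prefrontal"
 },
 {
  "name": "pars opercularis",
  "hemisphere": "lh",
  "lobe": "prefrontal"
 },
 {
  "name": "pars triangularis",
  "hemisphere": "lh",
  "lobe": "prefrontal"
 },
 {
  "name": "pars orbitalis",
  "hemisphere": "lh",
  "lobe": "prefrontal"
 },
 {
  "name": "lateral orbitofrontal",
  "hemisphere": "lh",
  "lobe": "prefrontal"
 },
 {
  "name": "medial orbitofrontal",
  "hemisphere": "lh",
  "lobe": "prefrontal"
 },
 {
  "name": "frontal pole",
  "hemisphere": "lh",
  "lobe": "prefrontal"
 },
 {
  "name": "anterior cingulate",
  "hemisphere": "lh",
  "lobe": "prefrontal"
 },
 {
  "name": "precentral",
  "hemisphere": "lh",
  "lobe": "motor_sensory"
 },
 {
  "name": "paracentral",
  "hemisphere": "lh",
  "lobe": "motor_sensory"
 },
 {
  "name": "postcentral gyrus",
  "hemisphere": "lh",
  "lobe": "motor_sensory"
 },
 {
  "name": "insular",
  "hemisphere": "lh",
  "lobe": "motor_sensory"
 },
 {
  "name": "lateral occipital",
  "hemisphere": "lh",
  "lobe": "occipital"
 },
 {
  "name": "lingual gyrus",
  "hemisphere": "lh",
  "lobe": "occipital"
 },
 {
  "name": "cuneus",
  "hemisphere": "lh",
  "lobe": "occipital"
 },
 {
  "name": "superior temporal",
  "hemisphere": "lh",
  "lobe": "lateral_temporal"
 },
 {
  "name": "transverse temporal",
  "hemisphere": "lh",
  "lobe": "lateral_temporal"
 },
 {
  "name": "middle temporal",
  "hemisphere": "lh",
  "lobe": "lateral_temporal"
 },
 {
  "name": "banks of superior temporal",
  "hemisphere": "lh",
  "lobe": "lateral_temporal"
 },
 {
  "name": "fusiform",
  "hemisphere": "lh",
  "lobe": "lateral_temporal"
 },
 {
  "name": "inferior temporal",
  "hemisphere": "lh",
  "lobe": "lateral_temporal"
 },
 {
  "name": "parahippocampus",
  "hemisphere": "lh",
  "lobe": "medial_temporal"
 },
 {
  "name": "temporal pole",
  "hemisphere": "lh",
  "lobe": "medial_temporal"
 },
 {
  "name": "entorhinal",
  "hemisphere": "lh",
  "lobe": "medial_temporal"
 },
 {
  "name": "hippocampus",
  "hemisphere": "lh",
  "lobe": "medial_temporal"
 },
 {
  "name": "amygdala",
  "hemisphere": "lh",
  "lobe": "medial_temporal"
 },
 {
  "name": "superior parietal",
  "hemisphere": "lh",
  "lobe": "parietal"
 },
 {
  "name": "supramarginal",
  "hemisphere": "lh",
  "lobe": "parietal"
 },
 {
  "name": "inferior parietal",
  "hemisphere": "lh",
  "lobe": "parietal"
 },
 {
  "name": "pericalcarine",
  "hemisphere": "lh",
  "lobe": "parietal"
 },
 {
  "name": "precuneus",
  "hemisphere": "lh",
  "lobe": "parietal"
 },
 {
  "name": "posterior cingulate",
  "hemisphere": "lh",
  "lobe": "parietal"
 },
 {
  "name": "striatum",
  "hemisphere": "lh",
  "lobe": "other"
 },
 {
  "name": "thalamus",
  "hemisphere": "lh",
  "lobe": "other"
 },
 {
  "name": "superior frontal",
  "hemisphere": "rh",
  "lobe": "prefrontal"
 },
 {
  "name": "caudal middle frontal",
  "hemisphere": "rh",
  "lobe": "prefrontal"
 },
 {
  "name": "rostral middle frontal",
  "hemisphere": "rh",
  "lobe": "prefrontal"
 },
 {
  "name": "pars opercularis",
  "hemisphere": "rh",
  "lobe": "prefrontal"
 },
 {
  "name": "pars triangularis",
  "hemisphere": "rh",
  "lobe": "prefrontal"
 },
 {
  "name": "pars orbitalis",
  "hemisphere": "rh",
  "lobe": "prefrontal"
 },
 {
  "name": "lateral orbitofrontal",
  "hemisphere": "rh",
  "lobe": "prefrontal"
 },
 {
  "name": "medial orbitofrontal",
  "hemisphere": "rh",
  "lobe": "prefrontal"
 },
 {
  "name": "frontal pole",
  "hemisphere": "rh",
  "lobe": "prefrontal"
 },
 {
  "name": "anterior cingulate",
  "hemisphere": "rh",
  "lobe": "prefrontal"
 },
 {
  "name": "precentral",
  "hemisphere": "rh",
  "lobe": "motor_sensory"
 },
 {
  "name": "paracentral",
  "hemisphere": "rh",
  "lobe": "motor_sensory"
 },
 {
  "name": "postcentral gyrus",
  "hemisphere": "rh",
  "lobe": "motor_sensory"
 },
 {
  "name": "insular",
  "hemisphere": "rh",
  "lobe": "motor_sensory"
 },
 {
  "name": "lateral occipital",
  "hemisphere": "rh",
  "lobe": "occipital"
 },
 {
  "name": "lingual gyrus",
  "hemisphere": "rh",
  "lobe": "occipital"
 },
 {
  "name": "cuneus",
  "hemisphere": "rh",
  "lobe": "occipital"
 },
 {
  "name": "superior temporal",
  "hemisphere": "rh",
  "lobe": "lateral_temporal"
 },
 {
  "name": "transverse temporal",
  "hemisphere": "rh",
  "lobe": "lateral_temporal"
 },
 {
  "name": "middle temporal",
  "hemisphere": "rh",
  "lobe": "lateral_temporal"
 },
 {
  "name": "banks of superior temporal",
  "hemisphere": "rh",
  "lobe": "lateral_temporal"
 },
 {
  "name": "fusiform",
  "hemisphere": "rh",
  "lobe": "lateral_temporal"
 },
 {
  "name": "inferior temporal",
  "hemisphere": "rh",
  "lobe": "lateral_temporal"
 },
 {
  "name": "parahippocampus",
  "hemisphere": "rh",
  "lobe": "medial_temporal"
 },
 {
  "name": "temporal pole",
  "hemisphere": "rh",
  "lobe": "medial_temporal"
 },
 {
  "name": "entorhinal",
  "hemisphere": "rh",
  "lobe": "medial_temporal"
 },
 {
  "name": "hippocampus",
  "hemisphere": "rh",
  "lobe": "medial_temporal"
 },
 {
  "name": "amygdala",
  "hemisphere": "rh",
  "lobe": "medial_temporal"
 },
 {
  "name": "superior parietal",
  "hemisphere": "rh",
  "lobe": "parietal"
 },
 {
  "name": "supramarginal",
  "hemisphere": "rh",
  "lobe": "parietal"
 },
 {
  "name": "inferior parietal",
  "hemisphere": "rh",
  "lobe": "parietal"
 },
 {
  "name": "pericalcarine",
  "hemisphere": "rh",
  "lobe": "parietal"
 },
 {
  "name": "precuneus",
  "hemisphere": "rh",
  "lobe": "parietal"
 },
 {
  "name": "posterior cingulate",
  "hemisphere": "rh",
  "lobe": "parietal"
 },
 {
  "name": "striatum",
  "hemisphere": "rh",
  "lobe": "other"
 },
 {
  "name": "thalamus",
  "hemisphere": "rh",
  "lobe": "other"
 }
]
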