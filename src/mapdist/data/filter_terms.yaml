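# Default curation vocabulary. Each list is overridable per run.
surgical_terms:
  - braces
  - resection
  - craniotomy
  - callosotomy
  - cingulotomy
  - lobotomy
  - hemicraniotomy
  - lobectomy
pathology_terms:
  - ischemia
  - tumor
  - stroke
  - ischemic
  - neurofibromatosis
  - infarct
  - glioblastoma
  - artifact
  - artifactual
  - mass effect
  - hyperintense
  - hyper intensity
negation_terms:
  - "no"
  - none
  - negative
  - "not"
  - without
  - inconsistent
  - normal
  - performed
  - obtained
  - acquired
  - unremarkable
series_exclude_strings:
  - tof
  - fl3d
  - memp
  - fse
  - grass
  - 3-Plane
  - gre
series_include_strings:
  - ep2
  - b
  - ep_
  - "1000"
  - directional
  - dif
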