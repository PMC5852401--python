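# Default comparison suite: the hierarchy of acquisition-parameter
# comparisons, from least to most restricted. Criteria omitted from an entry
# place no restriction on that parameter. Entries 1 and 2 compare the same
# pair of within-vendor distance distributions under both customary names
# (generation of the within-vendor sets vs. their between-vendor comparison).
- name: within_vendor
  criteria_a: {vendor: SIEMENS}
  criteria_b: {vendor: GE}
- name: between_vendor
  criteria_a: {vendor: SIEMENS}
  criteria_b: {vendor: GE}
- name: between_vendor_1p5T
  criteria_a: {vendor: SIEMENS, field_strength: 1.5}
  criteria_b: {vendor: GE, field_strength: 1.5}
- name: between_vendor_b1000
  criteria_a: {vendor: SIEMENS, b_value: 1000}
  criteria_b: {vendor: GE, b_value: 1000}
- name: siemens_b1000_vs_b700
  criteria_a: {vendor: SIEMENS, b_value: 1000}
  criteria_b: {vendor: SIEMENS, b_value: 700}
- name: siemens_1p5T_vs_3p0T
  criteria_a: {vendor: SIEMENS, field_strength: 1.5}
  criteria_b: {vendor: SIEMENS, field_strength: 3.0}
- name: between_vendor_b1000_30dir_1p5T
  criteria_a: {vendor: SIEMENS, b_value: 1000, n_directions: 30, field_strength: 1.5}
  criteria_b: {vendor: GE, b_value: 1000, n_directions: 30, field_strength: 1.5}
- name: siemens_b1000_30dir_1p5T_vs_3p0T
  criteria_a: {vendor: SIEMENS, b_value: 1000, n_directions: 30, field_strength: 1.5}
  criteria_b: {vendor: SIEMENS, b_value: 1000, n_directions: 30, field_strength: 3.0}
- name: ge_b1000_1p5T_6dir_vs_25dir
  criteria_a: {vendor: GE, b_value: 1000, field_strength: 1.5, n_directions: 6}
  criteria_b: {vendor: GE, b_value: 1000, field_strength: 1.5, n_directions: 25}
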