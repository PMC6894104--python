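Bayside Regional Hospital
Crestview Family Practice
Eastern Valley Clinic
Harbor Point Health Center
North Lake Clinic
Pine Grove Medical Institute
Riverbend Medical Center
South Ridge Hospital
Summit Care Hospital
Westgate Health Institute
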