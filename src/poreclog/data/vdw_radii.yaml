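# Default element-keyed Van der Waals radii in Å (Bondi 1964 values, with
# force-field-typical potassium). Used as radii.by_element fallback; override
# per atom name via the species config for force-field-specific radii.
H: 1.20
C: 1.70
N: 1.55
O: 1.52
P: 1.80
S: 1.80
F: 1.47
K: 1.76
CL: 1.75
NA: 2.27
MG: 1.73
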