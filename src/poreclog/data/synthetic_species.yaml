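# Species rules for trajectories written by poreclog.synthetic.
# Mobile "water" is a single bead (OW); walls (WL, residue WAL) are frozen
# spheres; obstruction beads (BD, residue OBS) emulate an inserted peptide.
# Radii are round synthetic values, not force-field radii.
species:
  water_residues: [SOL]
  ion_k_names: [K]
  ion_cl_names: [CL]
  pore_residues: [WAL]
  peptide_residues: [OBS]
charges:
  by_name:
    OW: 0.0
    K: 1.0
    CL: -1.0
    WL: 0.0
    BD: 0.0
  default: 0.0
radii:
  by_name:
    OW: 1.4
    K: 1.5
    CL: 1.8
    WL: 1.0
    BD: 3.0
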