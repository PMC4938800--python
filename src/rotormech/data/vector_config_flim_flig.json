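{
 "_comment": [
  "Vector configuration for hinge/interface angle measurements on the",
  "FliM_M-FliG_MC rotor switch complex (PDB 4FHR; FliM chain M, FliG chain G).",
  "Naming: M*/G* = FliM/FliG vectors, L = helix-axis line, P = plane normal,",
  "MGG = GGPG-motif loop vector.  The anchor residue ids below are visual",
  "estimates and are meant to be edited against the structure in hand; the",
  "pipeline treats them purely as data.",
  "Bending pairs: MP1.ML1, MP1.ML3, MP1.GP1, GP1.GL1, GP1.GL3.",
  "Rotation pairs (signed): ML2.MGG, ML0.GL0, GP2.GL2."
 ],
 "vectors": [
  {"name": "ML0", "kind": "line", "chain": "M", "res_ids": [46, 58]},
  {"name": "ML1", "kind": "line", "chain": "M", "res_ids": [60, 74]},
  {"name": "ML2", "kind": "line", "chain": "M", "res_ids": [78, 95]},
  {"name": "ML3", "kind": "line", "chain": "M", "res_ids": [180, 195]},
  {"name": "MP1", "kind": "plane_normal", "chain": "M", "res_ids": [60, 120, 180]},
  {"name": "MGG", "kind": "line", "chain": "M", "res_ids": [130, 137]},
  {"name": "GL0", "kind": "line", "chain": "G", "res_ids": [110, 122]},
  {"name": "GL1", "kind": "line", "chain": "G", "res_ids": [160, 175]},
  {"name": "GL2", "kind": "line", "chain": "G", "res_ids": [285, 298]},
  {"name": "GL3", "kind": "line", "chain": "G", "res_ids": [230, 245]},
  {"name": "GP1", "kind": "plane_normal", "chain": "G", "res_ids": [200, 215, 228]},
  {"name": "GP2", "kind": "plane_normal", "chain": "G", "res_ids": [250, 262, 274]}
 ],
 "pairs": [
  {"name": "bend_MP1_ML1", "a": "MP1", "b": "ML1"},
  {"name": "bend_MP1_ML3", "a": "MP1", "b": "ML3"},
  {"name": "bend_MP1_GP1", "a": "MP1", "b": "GP1"},
  {"name": "bend_GP1_GL1", "a": "GP1", "b": "GL1"},
  {"name": "bend_GP1_GL3", "a": "GP1", "b": "GL3"},
  {"name": "rot_ML2_MGG", "a": "ML2", "b": "MGG", "sign": "MP1"},
  {"name": "rot_ML0_GL0", "a": "ML0", "b": "GL0", "sign": "MP1"},
  {"name": "rot_GP2_GL2", "a": "GP2", "b": "GL2", "sign": "GP1"}
 ]
}
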