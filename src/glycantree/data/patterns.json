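[
  {"id": "lewis_a", "pattern": "Gal(b1-3)[Fuc(a1-4)]GlcNAc", "anchor": "anywhere",
   "note": "Lewis A determinant"},
  {"id": "lewis_x", "pattern": "Gal(b1-4)[Fuc(a1-3)]GlcNAc", "anchor": "anywhere",
   "note": "Lewis X determinant"},
  {"id": "lewis_b", "pattern": "Fuc(a1-2)Gal(b1-3)[Fuc(a1-4)]GlcNAc", "anchor": "anywhere",
   "note": "Lewis B determinant (two fucoses)"},
  {"id": "lewis_y", "pattern": "Fuc(a1-2)Gal(b1-4)[Fuc(a1-3)]GlcNAc", "anchor": "anywhere",
   "note": "Lewis Y determinant (two fucoses)"},
  {"id": "lewis_core_fuzzy", "pattern": "Gal[Fuc]GlcNAc[Fuc]", "anchor": "anywhere",
   "note": "linkage-free Lewis B/Y probe; with fuzzy matching it also retrieves structures whose linkages are unknown"},
  {"id": "lewis_mono_fuzzy", "pattern": "Gal GlcNAc[Fuc]", "anchor": "anywhere",
   "note": "linkage-free single-fucose Lewis A/X probe: Gal and Fuc on a GlcNAc"},
  {"id": "n_core", "pattern": "Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc", "anchor": "root",
   "note": "N-linked GlcNAc2Man3 core"},
  {"id": "o_core1", "pattern": "Gal(b1-3)GalNAc", "anchor": "root",
   "note": "O-linked Core 1 (T antigen)"},
  {"id": "sialyl_tn", "pattern": "Neu5Ac(a2-6)GalNAc", "anchor": "root",
   "note": "sialyl-Tn antigen"},
  {"id": "di_sialyl_tn", "pattern": "Neu5Ac(2-?)[Neu5Ac(2-?)]GalNAc", "anchor": "root",
   "note": "PROVISIONAL: two sialic acids on a GalNAc root; attachment positions deliberately unconstrained"}
]
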