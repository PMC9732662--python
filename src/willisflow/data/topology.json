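{
  "schema_version": 1,
  "name": "common-cow-33",
  "description": "Common arterial network: 18 intracranial segments covering the circle of Willis plus 15 main-body segments providing background flow. Default lengths and diameters are standard adult values; patient diameters override the defaults, a diameter of 0 marks an absent segment.",
  "inlet_node": "aorta_root",
  "terminal_nodes": [
    "l_mca_end", "r_mca_end",
    "l_aca_end", "r_aca_end",
    "l_pca_end", "r_pca_end",
    "l_arm", "r_arm",
    "l_leg", "r_leg"
  ],
  "segments": [
    {"id": 1,  "name": "ascending_aorta",    "group": "systemic", "default_length_m": 0.050, "default_diameter_mm": 28.0, "proximal_node": "aorta_root",    "distal_node": "arch_a"},
    {"id": 2,  "name": "aortic_arch_1",      "group": "systemic", "default_length_m": 0.025, "default_diameter_mm": 25.0, "proximal_node": "arch_a",        "distal_node": "arch_b"},
    {"id": 3,  "name": "aortic_arch_2",      "group": "systemic", "default_length_m": 0.030, "default_diameter_mm": 22.0, "proximal_node": "arch_b",        "distal_node": "desc_ao_start"},
    {"id": 4,  "name": "descending_aorta",   "group": "systemic", "default_length_m": 0.200, "default_diameter_mm": 20.0, "proximal_node": "desc_ao_start", "distal_node": "abd_junction"},
    {"id": 5,  "name": "abdominal_aorta",    "group": "systemic", "default_length_m": 0.150, "default_diameter_mm": 15.0, "proximal_node": "abd_junction",  "distal_node": "iliac_bif"},
    {"id": 6,  "name": "l_iliac",            "group": "systemic", "default_length_m": 0.100, "default_diameter_mm": 8.0,  "proximal_node": "iliac_bif",     "distal_node": "l_leg"},
    {"id": 7,  "name": "r_iliac",            "group": "systemic", "default_length_m": 0.100, "default_diameter_mm": 8.0,  "proximal_node": "iliac_bif",     "distal_node": "r_leg"},
    {"id": 8,  "name": "r_subclavian",       "group": "systemic", "default_length_m": 0.080, "default_diameter_mm": 8.0,  "proximal_node": "arch_a",        "distal_node": "r_arm"},
    {"id": 9,  "name": "l_subclavian",       "group": "systemic", "default_length_m": 0.080, "default_diameter_mm": 8.0,  "proximal_node": "arch_b",        "distal_node": "l_arm"},
    {"id": 10, "name": "r_common_carotid",   "group": "systemic", "default_length_m": 0.150, "default_diameter_mm": 7.0,  "proximal_node": "arch_a",        "distal_node": "r_carotid_bif"},
    {"id": 11, "name": "l_common_carotid",   "group": "systemic", "default_length_m": 0.130, "default_diameter_mm": 7.0,  "proximal_node": "arch_b",        "distal_node": "l_carotid_bif"},
    {"id": 12, "name": "r_ica_extracranial", "group": "systemic", "default_length_m": 0.130, "default_diameter_mm": 5.0,  "proximal_node": "r_carotid_bif", "distal_node": "r_ica_petrous"},
    {"id": 13, "name": "l_ica_extracranial", "group": "systemic", "default_length_m": 0.130, "default_diameter_mm": 5.0,  "proximal_node": "l_carotid_bif", "distal_node": "l_ica_petrous"},
    {"id": 14, "name": "r_vertebral_extracranial", "group": "systemic", "default_length_m": 0.150, "default_diameter_mm": 3.5, "proximal_node": "r_arm", "distal_node": "r_va_base"},
    {"id": 15, "name": "l_vertebral_extracranial", "group": "systemic", "default_length_m": 0.150, "default_diameter_mm": 3.5, "proximal_node": "l_arm", "distal_node": "l_va_base"},

    {"id": 16, "name": "r_ica",   "group": "cerebral", "default_length_m": 0.020, "default_diameter_mm": 4.0, "proximal_node": "r_ica_petrous", "distal_node": "r_ica_top"},
    {"id": 17, "name": "l_ica",   "group": "cerebral", "default_length_m": 0.020, "default_diameter_mm": 4.0, "proximal_node": "l_ica_petrous", "distal_node": "l_ica_top"},
    {"id": 18, "name": "r_m1",    "group": "cerebral", "default_length_m": 0.020, "default_diameter_mm": 3.0, "proximal_node": "r_ica_top",     "distal_node": "r_mca_end"},
    {"id": 19, "name": "l_m1",    "group": "cerebral", "default_length_m": 0.020, "default_diameter_mm": 3.0, "proximal_node": "l_ica_top",     "distal_node": "l_mca_end"},
    {"id": 20, "name": "r_a1",    "group": "cerebral", "default_length_m": 0.014, "default_diameter_mm": 2.2, "proximal_node": "r_ica_top",     "distal_node": "r_a1a2"},
    {"id": 21, "name": "l_a1",    "group": "cerebral", "default_length_m": 0.014, "default_diameter_mm": 2.2, "proximal_node": "l_ica_top",     "distal_node": "l_a1a2"},
    {"id": 22, "name": "acoa",    "group": "cerebral", "default_length_m": 0.003, "default_diameter_mm": 1.5, "proximal_node": "l_a1a2",        "distal_node": "r_a1a2"},
    {"id": 23, "name": "r_a2",    "group": "cerebral", "default_length_m": 0.025, "default_diameter_mm": 2.2, "proximal_node": "r_a1a2",        "distal_node": "r_aca_end"},
    {"id": 24, "name": "l_a2",    "group": "cerebral", "default_length_m": 0.025, "default_diameter_mm": 2.2, "proximal_node": "l_a1a2",        "distal_node": "l_aca_end"},
    {"id": 25, "name": "r_pcoma", "group": "cerebral", "default_length_m": 0.015, "default_diameter_mm": 1.4, "proximal_node": "r_ica_top",     "distal_node": "r_p1p2"},
    {"id": 26, "name": "l_pcoma", "group": "cerebral", "default_length_m": 0.015, "default_diameter_mm": 1.4, "proximal_node": "l_ica_top",     "distal_node": "l_p1p2"},
    {"id": 27, "name": "r_vertebral_intracranial", "group": "cerebral", "default_length_m": 0.035, "default_diameter_mm": 3.0, "proximal_node": "r_va_base", "distal_node": "ba_junction"},
    {"id": 28, "name": "l_vertebral_intracranial", "group": "cerebral", "default_length_m": 0.035, "default_diameter_mm": 3.0, "proximal_node": "l_va_base", "distal_node": "ba_junction"},
    {"id": 29, "name": "ba",      "group": "cerebral", "default_length_m": 0.030, "default_diameter_mm": 3.2, "proximal_node": "ba_junction",   "distal_node": "ba_top"},
    {"id": 30, "name": "r_p1",    "group": "cerebral", "default_length_m": 0.010, "default_diameter_mm": 2.2, "proximal_node": "ba_top",        "distal_node": "r_p1p2"},
    {"id": 31, "name": "l_p1",    "group": "cerebral", "default_length_m": 0.010, "default_diameter_mm": 2.2, "proximal_node": "ba_top",        "distal_node": "l_p1p2"},
    {"id": 32, "name": "r_p2",    "group": "cerebral", "default_length_m": 0.025, "default_diameter_mm": 2.1, "proximal_node": "r_p1p2",        "distal_node": "r_pca_end"},
    {"id": 33, "name": "l_p2",    "group": "cerebral", "default_length_m": 0.025, "default_diameter_mm": 2.1, "proximal_node": "l_p1p2",        "distal_node": "l_pca_end"}
  ]
}
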