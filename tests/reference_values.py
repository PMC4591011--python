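"""Published reference values used as fixed inputs by the acceptance tests.

Each row gives printed measurements from the source study's report; they are
treated as inputs (not recomputed quantities). SR columns are per-tissue
log2 response scores; NORM is the printed composite Euclidean norm.
"""

# ovary genes: (label, rpkm_gc, rpkm_sf, printed_sr)
OVARY_RPKM_ROWS = [
    ("1-sf", 7.23, 2.22, -1.70),
    ("ZP2(1of3)", 457.84, 355.68, -0.36),
    ("ZP2(2of3)", 2068.80, 2059.62, -0.01),
    ("ZP2(3of3)", 1223.85, 1321.62, 0.11),
    ("zp3b", 678.32, 710.87, 0.07),
    ("chgHm", 1.61, 0.65, -1.31),
    ("chgH", 7.42, 2.61, -1.51),
    ("ZPB", 1824.70, 1722.53, -0.08),
    ("ZPC3", 907.89, 876.16, -0.05),
]

# multi-tissue responders: (gene, (sr_brain, sr_eye, sr_ovary, sr_testis,
# sr_liver, sr_intestine), printed_norm)
MULTI_TISSUE_SR_ROWS = [
    ("dusp1", (1.31, 1.12, 1.18, 0.40, 1.02, 0.81), 2.49),
    ("hif1a1", (0.31, 0.28, 1.25, 1.42, 1.49, 1.30), 2.76),
    ("hsp70.3", (2.06, 2.14, -0.16, -0.34, 2.57, 1.47), 4.21),
    ("keap1a", (-0.13, -0.41, -1.51, -1.52, -1.00, -1.11), 2.64),
    ("klf9", (2.69, 2.72, 0.59, 0.40, 4.48, 4.34), 7.35),
    ("klf13", (2.06, 1.25, 0.35, 1.35, 1.88, 2.56), 4.22),
    ("mat2ab", (0.23, 0.10, 1.44, 1.26, 2.36, 1.22), 3.28),
    ("nrld4b", (-0.02, 1.29, 1.38, 1.68, 0.34, 1.16), 2.80),
    ("odc1", (-0.43, -0.23, 2.04, 1.04, 2.44, 3.07), 4.57),
    ("tmem39a", (0.21, -0.11, 1.34, 1.14, 1.98, 1.05), 2.86),
    ("usp10", (-0.36, -0.24, 1.19, 1.07, 1.46, 1.06), 2.45),
    ("zfp36", (1.76, 1.55, 1.28, 0.31, -0.27, 1.84), 3.27),
]

# focal-tissue (intestine) dominant responders: (gene, (sr_intestine,
# sr_brain, sr_eye, sr_ovary, sr_testis, sr_liver), printed_norm)
FOCAL_TISSUE_SR_ROWS = [
    ("prdx1", (4.66, -0.15, 0.07, -0.42, -0.36, 0.53), 4.72),
    ("GSTO1", (3.43, -0.27, -0.05, -0.32, -0.64, -0.07), 3.52),
    ("cyba", (3.45, -0.60, -0.46, -1.29, 0.11, -0.48), 3.79),
    ("steap3", (3.43, -0.20, 0.11, -0.06, -0.20, 0.17), 3.45),
    ("pgd", (3.02, -0.19, -0.16, 0.45, 0.28, 0.21), 3.08),
    ("arf2", (2.79, -0.13, 0.03, 0.42, 0.17, 0.02), 2.83),
    ("txndc2", (2.52, 0.08, 0.17, 0.08, -0.27, -0.16), 2.55),
    ("scdb", (-2.76, -0.26, -0.17, 1.01, 0.80, 0.47), 3.10),
    ("hsd11b1l", (-2.88, -0.02, -0.39, -0.77, 0.31, -0.69), 3.10),
    ("cdo1", (-5.83, 0.14, 0.72, -2.12, -0.21, -0.67), 6.28),
]

# rows where two-decimal rounding of the printed SR inputs reproduces the
# printed norm exactly at two decimals
EXACT_NORM_GENES = {"klf9", "hsp70.3", "odc1", "GSTO1"}

# per-tissue twofold responder counts: tissue -> (up, down, total examined)
TISSUE_TWOFOLD_COUNTS = {
    "brain": (91, 45, 13528),
    "eye": (112, 84, 14459),
    "ovary": (1562, 240, 10836),
    "testis": (731, 249, 11887),
    "liver": (378, 648, 7385),
    "intestine": (2279, 492, 9905),
}
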