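"""Reference panel constants for the study cohort emulated by the generator.

Geometric means (GM) and observed ranges per group for the reported plasma
panel: non-esterified fatty acids (uM), oxylipins (nM) and
N-acylethanolamide / lipoamino-acid endocannabinoids (nM), in overweight
non-diabetic (n = 12) and type 2 diabetic (n = 43) women.  Class-total
("sigma") rows are carried as their own anchored variables.

Entries: name -> (chem_class, carbons, double_bonds, unit,
                  gm_nd, (lo_nd, hi_nd), gm_d, (lo_d, hi_d))

A few NEFA species required by the enzyme-activity indices were not
reported individually; their GMs are back-derived from the reported
product:substrate ratio GMs for internal consistency and are marked below.
Four further index metabolites are produced by pathway couplings (see
:func:`lipidcohort.synth.default_paper_spec`) rather than anchored here.
"""

from __future__ import annotations

# -- NEFA panel (uM) --------------------------------------------------------
NEFA = {
    "Σ NEFA": ("aggregate", 0, 0, "uM", 290.0, (109.0, 653.0), 621.0, (182.0, 1960.0)),
    "Σ SFA": ("aggregate", 0, 0, "uM", 135.0, (47.0, 341.0), 281.0, (79.0, 787.0)),
    "14:0": ("SFA", 14, 0, "uM", 2.93, (1.0, 19.0), 5.48, (1.0, 18.0)),
    "16:0": ("SFA", 16, 0, "uM", 92.7, (30.0, 260.0), 196.0, (46.0, 582.0)),
    "18:0": ("SFA", 18, 0, "uM", 38.7, (14.0, 66.0), 79.7, (30.0, 197.0)),
    "19:0": ("SFA", 19, 0, "uM", 0.05, (0.02, 0.13), 0.09, (0.03, 0.37)),
    "20:0": ("SFA", 20, 0, "uM", 0.12, (0.05, 0.43), 0.21, (0.01, 2.82)),
    "Σ MUFA": ("aggregate", 0, 1, "uM", 54.8, (21.6, 124.0), 176.0, (48.0, 682.0)),
    "16:1n7": ("MUFA", 16, 1, "uM", 3.08, (1.0, 17.0), 8.78, (3.0, 38.0)),
    "18:1n7": ("MUFA", 18, 1, "uM", 5.68, (3.0, 10.0), 15.0, (5.0, 49.0)),
    "18:1n9": ("MUFA", 18, 1, "uM", 45.1, (18.0, 95.0), 150.0, (40.0, 620.0)),
    "20:1n9": ("MUFA", 20, 1, "uM", 0.37, (0.10, 0.65), 1.40, (0.14, 6.50)),
    "Σ PUFA": ("aggregate", 0, 2, "uM", 99.2, (41.0, 185.0), 162.0, (33.0, 579.0)),
    "18:2n6": ("PUFA", 18, 2, "uM", 54.8, (24.0, 102.0), 103.0, (22.0, 363.0)),
    "9c,11t-CLA": ("PUFA", 18, 2, "uM", 0.85, (0.32, 2.0), 1.29, (0.34, 4.0)),
    "18:3n3": ("PUFA", 18, 3, "uM", 1.57, (0.34, 9.0), 4.02, (1.0, 16.0)),
    "22:4n6": ("PUFA", 22, 4, "uM", 0.42, (0.03, 2.0), 0.74, (0.05, 3.0)),
    "22:5n3": ("PUFA", 22, 5, "uM", 1.15, (0.12, 3.0), 2.17, (0.28, 9.0)),
    "trans-16:1n7": ("trans-FA", 16, 1, "uM", 0.76, (0.19, 2.5), 2.04, (0.5, 9.0)),
    "trans-18:2n6": ("trans-FA", 18, 2, "uM", 0.28, (0.03, 1.0), 1.17, (0.05, 4.0)),
    # Back-derived anchors (not reported individually):
    # 20:5n3 from 22:5n3 GMs and the 22:5n3/20:5n3 ratio GMs (0.82, 1.40);
    # 20:4n6 from 22:4n6 GMs and the 22:4n6/20:4n6 ratio GMs (0.02, 0.03).
    "20:5n3": ("PUFA", 20, 5, "uM", 1.40, (0.4, 4.0), 1.55, (0.4, 5.0)),
    "20:4n6": ("PUFA", 20, 4, "uM", 21.0, (8.0, 50.0), 24.7, (8.0, 65.0)),
}

# -- Oxylipins (nM) ---------------------------------------------------------
OXYLIPINS = {
    "9(10)-EpODE": ("epoxide", 18, 2, "nM", 0.32, (0.10, 4.0), 0.66, (0.10, 6.0)),
    "9(10)-EpOME": ("epoxide", 18, 1, "nM", 1.18, (0.30, 11.0), 2.68, (0.70, 20.0)),
    "12(13)-EpOME": ("epoxide", 18, 1, "nM", 1.43, (0.50, 12.0), 2.76, (0.70, 17.0)),
    "EKODE": ("ketone", 18, 2, "nM", 1.69, (0.80, 18.0), 2.43, (0.20, 14.0)),
    "11(12)-EpETrE": ("epoxide", 20, 3, "nM", 0.46, (0.20, 2.0), 0.70, (0.10, 4.0)),
    "14(15)-EpETrE": ("epoxide", 20, 3, "nM", 0.24, (0.10, 1.0), 0.35, (0.10, 2.0)),
    "11,12-DiHETrE": ("diol", 20, 3, "nM", 0.44, (0.32, 0.70), 0.62, (0.34, 1.24)),
    "14,15-DiHETrE": ("diol", 20, 3, "nM", 0.52, (0.38, 0.72), 0.67, (0.38, 1.44)),
    "13-KODE": ("ketone", 18, 2, "nM", 5.63, (3.0, 25.0), 10.5, (0.80, 68.0)),
}

# -- Endocannabinoids: NAE and LAA (nM) -------------------------------------
ENDOCANNABINOIDS = {
    "Σ NAE": ("aggregate", 0, 0, "nM", 67.4, (27.0, 124.0), 106.0, (25.0, 440.0)),
    "P-EA": ("NAE", 16, 0, "nM", 9.59, (5.0, 40.0), 18.9, (6.0, 162.0)),
    "O-EA": ("NAE", 18, 1, "nM", 20.3, (8.0, 33.0), 36.2, (9.0, 175.0)),
    "L-EA": ("NAE", 18, 2, "nM", 7.91, (4.0, 27.0), 11.4, (5.0, 44.0)),
    "DGL-EA": ("NAE", 20, 3, "nM", 0.50, (0.30, 1.0), 0.93, (0.30, 4.0)),
    "A-EA": ("NAE", 20, 4, "nM", 2.09, (1.0, 3.0), 3.57, (1.0, 8.0)),
    "DoP-EA": ("NAE", 22, 5, "nM", 1.29, (0.20, 2.76), 1.97, (0.68, 4.66)),
    "DoHex-EA": ("NAE", 22, 6, "nM", 0.55, (0.30, 1.0), 1.02, (0.40, 2.0)),
    "Σ LAA": ("aggregate", 0, 0, "nM", 8.67, (2.50, 36.1), 21.0, (4.50, 88.6)),
    "NO-Gly": ("LAA", 18, 1, "nM", 8.15, (2.0, 34.0), 20.2, (4.0, 86.0)),
}

PANEL = {**NEFA, **OXYLIPINS, **ENDOCANNABINOIDS}

#: Metabolites generated via pathway couplings at the reported ratio GMs:
#: (substrate, product, enzyme, ratio_gm_nd, ratio_gm_d, annotation)
COUPLED = [
    ("18:2n6", "18:3n6", "D6D", 0.01, 0.01, ("PUFA", 18, 3, "uM")),
    ("20:4n6", "20:3n3", "D6D-index", 0.15, 0.16, ("PUFA", 20, 3, "uM")),
    ("22:4n6", "22:5n6", "ELOVL2/D6D/SPCS", 3.12, 1.37, ("PUFA", 22, 5, "uM")),
    ("22:5n3", "22:6n3", "ELOVL2/D6D/SPCS", 8.76, 6.15, ("PUFA", 22, 6, "uM")),
]

#: Reported activity-index geometric means per group (non-diabetic,
#: diabetic): composite indices and their component product:substrate
#: ratios.  Components with reported "ND" bounds carry only GMs here.
INDEX_GM = {
    "SCD": (0.60, 0.96),
    "16:1n7/16:0": (0.03, 0.04),
    "18:1n9/18:0": (1.16, 1.88),
    "D6D": (0.08, 0.08),
    "18:3n6/18:2n6": (0.01, 0.01),
    "20:3n3/20:4n6": (0.15, 0.16),
    "ELOVL2": (0.42, 0.72),
    "22:4n6/20:4n6": (0.02, 0.03),
    "22:5n3/20:5n3": (0.82, 1.40),
    "ELOVL2/D6D/SPCS": (6.71, 3.99),
    "22:5n6/22:4n6": (3.12, 1.37),
    "22:6n3/22:5n3": (8.76, 6.15),
}

#: Biosynthetic edges drawn in the pathway graph (substrate, product, enzyme).
PATHWAY_EDGES = [
    ("16:0", "16:1n7", "SCD"),
    ("18:0", "18:1n9", "SCD"),
    ("18:2n6", "18:3n6", "D6D"),
    ("20:4n6", "22:4n6", "ELOVL2"),
    ("20:5n3", "22:5n3", "ELOVL2"),
    ("22:4n6", "22:5n6", "ELOVL2/D6D/SPCS"),
    ("22:5n3", "22:6n3", "ELOVL2/D6D/SPCS"),
    ("18:1n9", "O-EA", "NAE synthesis"),
    ("18:1n9", "NO-Gly", "LAA synthesis"),
    ("20:4n6", "A-EA", "NAE synthesis"),
    ("16:0", "P-EA", "NAE synthesis"),
    ("18:2n6", "L-EA", "NAE synthesis"),
]

#: Clinical covariates: name -> ((mean_nd, sd_nd), (mean_d, sd_d), units,
#: target Spearman rho, anchor variable).  Glucose is rank-coupled to total
#: NEFA at rho = 0.68 (the reported fasting glucose association); HbA1c
#: tracks the same axis more loosely.
CLINICAL = {
    "Body mass": ((89.3, 17.0), (92.7, 17.0), "kg", None, None),
    "BMI": ((33.0, 6.0), (36.0, 6.0), "kg/m2", None, None),
    "Age": ((49.0, 17.0), (55.0, 14.0), "yr", None, None),
    "Glucose": ((92.0, 10.0), (210.0, 79.0), "mg/dL", 0.68, "Σ NEFA"),
    "HbA1c": ((5.4, 1.0), (9.1, 2.0), "%", 0.50, "Σ NEFA"),
    "Lactate": ((1.1, 0.2), (1.2, 0.2), "mmol/L", None, None),
    "Triglycerides": ((100.0, 61.0), (120.0, 75.0), "mg/dL", None, None),
    "Cholesterol": ((200.0, 52.0), (210.0, 47.0), "mg/dL", None, None),
    "HDL cholesterol": ((45.0, 12.0), (44.0, 13.0), "mg/dL", None, None),
    "LDL cholesterol": ((140.0, 42.0), (140.0, 41.0), "mg/dL", None, None),
    "VLDL cholesterol": ((20.0, 12.0), (23.0, 15.0), "mg/dL", None, None),
}

GROUP_LABELS = ("non-diabetic", "type 2 diabetic")
N_PER_GROUP = (12, 43)
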