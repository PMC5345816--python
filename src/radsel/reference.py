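"""Published worked-example inputs.

Random-forest importance coefficients reported for the original
65-patient esophageal-cancer cohort this workflow was developed on:
nine predictive (treatment-response) and eight prognostic (3-year
survival) coefficients, already ordered by rank. They serve as inputs to
the 10%-of-maximum threshold rule in the worked example and the
acceptance checks; they are data, not results computed here.
"""

PREDICTIVE_IMPORTANCE: list[tuple[str, float]] = [
    ("MTV", 0.534),
    ("GLSZM_GLNUz", 0.319),
    ("GLDM_busyness", 0.236),
    ("Energy", 0.220),
    ("GLCM_homogeneity", 0.181),
    ("Weight_loss", 0.166),
    ("Weight_usual", 0.128),
    ("WHO_status", 0.114),
    ("GLCM_contrast", 0.071),
]

PROGNOSTIC_IMPORTANCE: list[tuple[str, float]] = [
    ("NRI", 0.272),
    ("Age", 0.257),
    ("WHO_status", 0.200),
    ("Weight_loss", 0.155),
    ("MTV", 0.149),
    ("Tumor_location", 0.089),
    ("GLSZM_SZE", 0.081),
    ("Energy", 0.077),
]
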