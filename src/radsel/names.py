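"""Canonical feature names for the 61-feature cohort table.

16 clinical covariates (categoricals numerically encoded upstream),
19 first-order image features, and 26 texture indices. CSV output and
the selection stages use these names verbatim.
"""

CLINICAL_FEATURES = [
    "Age",
    "Gender",
    "Albumin",
    "NRI",
    "Malnutrition",
    "Weight_current",
    "Weight_usual",
    "Weight_loss",
    "Tumor_location",
    "Histology",
    "T_stage",
    "N_stage",
    "M_stage",
    "Clinical_stage",
    "WHO_status",
    "Tumor_length",
]

FIRST_ORDER_FEATURES = [
    "SUV_max",
    "SUV_mean",
    "SUV_peak",
    "SUV_sum",
    "MTV",
    "TLG",
    "SD",
    "COV",
    "Sphericity",
    "Skewness",
    "Kurtosis",
    "Energy",
    "Entropy",
    "SUV_10",
    "SUV_90",
    "SUV_10-SUV_90",
    "V_10",
    "V_90",
    "V_10-V_90",
]

TEXTURE_FEATURES = [
    "GLCM_variance",
    "GLCM_energy",
    "GLCM_entropy",
    "GLCM_correlation",
    "GLCM_dissimilarity",
    "GLCM_contrast",
    "GLCM_homogeneity",
    "GLCM_IDM",
    "GLCM_cluster_shade",
    "GLCM_cluster_tendency",
    "GLSZM_SZE",
    "GLSZM_LZE",
    "GLSZM_LGZE",
    "GLSZM_HGZE",
    "GLSZM_SZLGE",
    "GLSZM_LZLGE",
    "GLSZM_SZHGE",
    "GLSZM_LZHGE",
    "GLSZM_ZP",
    "GLSZM_GLNUz",
    "GLSZM_ZLNU",
    "GLDM_coarseness",
    "GLDM_contrast",
    "GLDM_busyness",
    "GLDM_complexity",
    "GLDM_strength",
]

ALL_FEATURES = CLINICAL_FEATURES + FIRST_ORDER_FEATURES + TEXTURE_FEATURES

#: Default robustness priority for choosing a correlation-group leader.
#: Features earlier in the list are considered more robust to image
#: reconstruction settings. This ordering is package-supplied data (the
#: robustness experiment itself is out of scope) and is overridable; it
#: places the established group leaders — volume and simple intensity
#: statistics, nutritional covariates, and the most reproducible texture
#: indices — ahead of the features known to track them.
DEFAULT_ROBUSTNESS_PRIORITY = [
    # group leaders first: clinical anchors, then robust image features
    "Weight_usual",
    "NRI",
    "V_10-V_90",
    "GLSZM_ZLNU",
    "Energy",
    "MTV",
    "SUV_max",
    "GLCM_homogeneity",
    "GLDM_busyness",
] + [f for f in ALL_FEATURES if f not in {
    "Weight_usual", "NRI", "V_10-V_90", "GLSZM_ZLNU", "Energy",
    "MTV", "SUV_max", "GLCM_homogeneity", "GLDM_busyness",
}]
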