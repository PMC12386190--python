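"""Published reference values for the PAX3 nasal-root association study.

Per-population regression estimates (coefficient B and its standard
error) for the three model families, allele and haplotype frequencies,
and measurement summaries for the Japanese cohort.  Subject-level data
from the original study are not publicly deposited, so these summary
statistics serve two roles here:

* inputs to the meta-analysis (the combined columns are recomputed from
  the per-population pairs at run time, never stored);
* calibration targets and cross-checks for the synthetic-cohort
  generator and the population-genetics routines.
"""
from __future__ import annotations

POPULATIONS = ("Japanese", "Korean", "Egyptian")

SAMPLE_SIZES = {"Japanese": 201, "Korean": 74, "Egyptian": 142}

#: (male, female) counts per population.
SEX_COUNTS = {"Japanese": (56, 145), "Korean": (29, 45), "Egyptian": (63, 79)}

#: Derived-allele frequencies per SNP and population.
DERIVED_ALLELE_FREQ = {
    "rs9288572": {"Japanese": 0.572, "Korean": 0.561, "Egyptian": 0.197},
    "rs7559271": {"Japanese": 0.701, "Korean": 0.649, "Egyptian": 0.532},
}

#: Two-SNP haplotype frequencies per population (hXY: first letter the
#: rs9288572 allele, second the rs7559271 allele).
HAPLOTYPE_FREQ = {
    "Japanese": {"hAG": 0.419, "hAA": 0.153, "hGG": 0.283, "hGA": 0.145},
    "Korean": {"hAG": 0.384, "hAA": 0.177, "hGG": 0.265, "hGA": 0.174},
    "Egyptian": {"hAG": 0.108, "hAA": 0.089, "hGG": 0.424, "hGA": 0.379},
}

#: Single-SNP model: {(rs id, variable): {population: (B, SE)}}.
#: B is in the outcome's units per derived allele; the reported
#: dispersion column is the coefficient's standard error.
SINGLE_SNP = {
    ("rs9288572", "g-n-rhi"): {"Japanese": (1.090, 0.606), "Korean": (0.426, 0.894), "Egyptian": (0.950, 1.12)},
    ("rs9288572", "md-n-g"): {"Japanese": (-1.621, 0.684), "Korean": (0.616, 1.197), "Egyptian": (-0.470, 1.216)},
    ("rs9288572", "s-n-g"): {"Japanese": (-0.784, 0.485), "Korean": (0.833, 0.859), "Egyptian": (-0.010, 0.884)},
    ("rs9288572", "s-n-rhi"): {"Japanese": (-0.260, 0.571), "Korean": (-1.270, 0.859), "Egyptian": (-0.992, 0.875)},
    ("rs9288572", "s-n-md"): {"Japanese": (-0.799, 0.576), "Korean": (-0.242, 0.923), "Egyptian": (-0.365, 0.997)},
    ("rs9288572", "dR-n-dL"): {"Japanese": (0.468, 0.908), "Korean": (-1.265, 1.304), "Egyptian": (1.560, 1.15)},
    ("rs9288572", "dR-s-dL"): {"Japanese": (-0.111, 0.199), "Korean": (-0.469, 0.329), "Egyptian": (0.288, 0.318)},
    ("rs9288572", "n-md/dR-dL"): {"Japanese": (-0.003, 0.009), "Korean": (0.014, 0.013), "Egyptian": (-0.017, 0.013)},
    ("rs7559271", "g-n-rhi"): {"Japanese": (0.258, 0.675), "Korean": (-0.440, 0.994), "Egyptian": (0.720, 0.815)},
    ("rs7559271", "md-n-g"): {"Japanese": (-1.878, 0.758), "Korean": (1.660, 1.328), "Egyptian": (-2.469, 0.863)},
    ("rs7559271", "s-n-g"): {"Japanese": (-1.343, 0.533), "Korean": (1.930, 0.941), "Egyptian": (-1.941, 0.624)},
    ("rs7559271", "s-n-rhi"): {"Japanese": (1.090, 0.629), "Korean": (-1.469, 0.963), "Egyptian": (1.214, 0.636)},
    ("rs7559271", "s-n-md"): {"Japanese": (-0.519, 0.641), "Korean": (-0.354, 1.032), "Egyptian": (-0.504, 0.727)},
    ("rs7559271", "dR-n-dL"): {"Japanese": (1.836, 0.997), "Korean": (0.601, 1.467), "Egyptian": (0.270, 0.848)},
    ("rs7559271", "dR-s-dL"): {"Japanese": (0.114, 0.221), "Korean": (0.557, 0.368), "Egyptian": (-0.217, 0.232)},
    ("rs7559271", "n-md/dR-dL"): {"Japanese": (-0.019, 0.010), "Korean": (-0.005, 0.015), "Egyptian": (-0.002, 0.009)},
}

#: Haplotype-copy model (reference hGA): {(haplotype, variable): ...}.
HAPLOTYPE_MODEL = {
    ("hAG", "md-n-g"): {"Japanese": (-3.296, 0.968), "Korean": (1.127, 2.137), "Egyptian": (-2.974, 1.553)},
    ("hAA", "md-n-g"): {"Japanese": (-2.643, 1.291), "Korean": (-0.537, 2.380), "Egyptian": (-0.104, 1.782)},
    ("hGG", "md-n-g"): {"Japanese": (-2.496, 1.063), "Korean": (1.491, 2.183), "Egyptian": (-2.379, 0.948)},
    ("hAG", "s-n-g"): {"Japanese": (-1.702, 0.686), "Korean": (1.984, 1.493), "Egyptian": (-2.180, 1.121)},
    ("hAA", "s-n-g"): {"Japanese": (0.282, 0.914), "Korean": (1.147, 1.663), "Egyptian": (0.765, 1.287)},
    ("hGG", "s-n-g"): {"Japanese": (-0.628, 0.753), "Korean": (3.292, 1.525), "Egyptian": (-1.737, 0.685)},
}

#: Multi-SNP model with interaction: {(term, variable): ...}.
MULTI_SNP = {
    ("rs9288572", "md-n-g"): {"Japanese": (-2.922, 1.631), "Korean": (0.087, 2.914), "Egyptian": (0.787, 2.005)},
    ("rs7559271", "md-n-g"): {"Japanese": (-2.893, 1.429), "Korean": (1.375, 2.234), "Egyptian": (-2.075, 1.017)},
    ("interaction", "md-n-g"): {"Japanese": (1.101, 1.078), "Korean": (0.225, 1.819), "Egyptian": (-1.115, 1.524)},
    ("rs9288572", "s-n-g"): {"Japanese": (0.080, 1.158), "Korean": (-0.847, 2.049), "Egyptian": (0.452, 1.453)},
    ("rs7559271", "s-n-g"): {"Japanese": (-0.669, 1.014), "Korean": (0.866, 1.571), "Egyptian": (-1.809, 0.736)},
    ("interaction", "s-n-g"): {"Japanese": (-0.513, 0.765), "Korean": (0.994, 1.279), "Egyptian": (-0.380, 1.104)},
}

#: Japanese measurement summaries {variable: (mean, SD)}, used to
#: calibrate the synthetic landmark template and its noise level.
JAPANESE_MALE_SUMMARY = {
    "n-me": (126.03, 5.92), "n-ans": (56.25, 3.08), "a-ba": (90.95, 5.24),
    "n-ba": (102.54, 4.53), "n-s": (66.47, 2.79), "poR-poL": (124.60, 5.61),
    "sorR-sorL": (59.54, 3.29), "fzsR-fzsL": (104.84, 4.94),
    "orR-orL": (60.44, 3.76), "dR-dL": (19.36, 1.99), "n-g": (11.94, 2.13),
    "n-rhi": (26.28, 3.96), "n-md": (11.53, 1.98),
    "g-n-rhi": (138.54, 7.95), "md-n-g": (150.69, 8.36), "s-n-g": (113.43, 5.83),
    "s-n-rhi": (107.95, 6.66), "s-n-md": (37.45, 6.75), "dR-n-dL": (80.71, 10.88),
    "dR-s-dL": (18.97, 2.07), "n-md/dR-dL": (0.60, 0.11),
}

JAPANESE_FEMALE_SUMMARY = {
    "n-me": (118.63, 5.64), "n-ans": (52.12, 2.46), "a-ba": (85.86, 4.52),
    "n-ba": (96.53, 4.13), "n-s": (62.64, 2.74), "poR-poL": (117.18, 4.84),
    "sorR-sorL": (57.69, 2.80), "fzsR-fzsL": (99.88, 3.53),
    "orR-orL": (57.91, 3.59), "dR-dL": (18.59, 1.86), "n-g": (13.96, 3.14),
    "n-rhi": (24.95, 2.85), "n-md": (10.43, 1.48),
    "g-n-rhi": (147.84, 5.11), "md-n-g": (147.00, 6.20), "s-n-g": (106.16, 4.40),
    "s-n-rhi": (105.93, 5.19), "s-n-md": (41.02, 5.29), "dR-n-dL": (83.75, 8.13),
    "dR-s-dL": (19.09, 1.94), "n-md/dR-dL": (0.56, 0.08),
}
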