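"""Published reference measurements for the two *Tulipa* taxa.

These are the printed species-level tables from the source study of the
rediscovered Greek population of *Tulipa scardica* compared against
*T. undulatifolia*: per-pair mean chromosome arm lengths, species-level
karyomorphometric index summaries (mean, SD, number of metaphase plates),
quantitative morphological trait summaries (mean, SD per species), and seed
morphometric summaries. They parameterize the synthetic-data generators and
anchor the desk-scale recomputations; the underlying per-plate and
per-individual raw measurements were not published.
"""

from __future__ import annotations

SCARDICA = "T_scardica"
UNDULATIFOLIA = "T_undulatifolia"

#: Mean long/short arm lengths (um) per homologous pair, largest to smallest.
#: Each entry: (pair_index, long_arm, short_arm).
CHROMOSOME_ARMS: dict[str, list[tuple[int, float, float]]] = {
    SCARDICA: [
        (1, 10.02, 3.89),
        (2, 9.32, 4.06),
        (3, 9.44, 3.52),
        (4, 9.02, 3.30),
        (5, 8.80, 2.84),
        (6, 8.07, 2.97),
        (7, 7.48, 3.11),
        (8, 7.32, 2.64),
        (9, 6.87, 3.10),
        (10, 7.13, 2.51),
        (11, 6.73, 2.34),
        (12, 6.56, 2.00),
    ],
    UNDULATIFOLIA: [
        (1, 10.53, 4.52),
        (2, 10.25, 3.93),
        (3, 9.92, 3.69),
        (4, 9.60, 3.53),
        (5, 9.15, 3.15),
        (6, 8.45, 2.95),
        (7, 7.97, 2.74),
        (8, 7.45, 2.89),
        (9, 7.36, 2.57),
        (10, 6.75, 2.68),
        (11, 6.60, 2.45),
        (12, 6.10, 2.43),
    ],
}

#: Printed per-pair ratio columns (r-index, centromeric index, arm difference
#: ratio, relative length). These were computed on per-plate measurements
#: before averaging and are therefore NOT reproducible from the mean arm
#: lengths above; they are kept for the internal-consistency checks
#: (adr = 2*ci - 1 holds on the printed values at printed precision).
CHROMOSOME_RATIOS: dict[str, list[tuple[int, float, float, float, float]]] = {
    SCARDICA: [
        (1, 2.86, 0.716, 0.432, 0.052),
        (2, 2.68, 0.700, 0.400, 0.050),
        (3, 2.94, 0.731, 0.463, 0.049),
        (4, 2.77, 0.731, 0.462, 0.046),
        (5, 3.27, 0.753, 0.506, 0.044),
        (6, 3.11, 0.733, 0.466, 0.041),
        (7, 2.48, 0.705, 0.410, 0.040),
        (8, 3.02, 0.739, 0.479, 0.038),
        (9, 2.27, 0.689, 0.378, 0.038),
        (10, 3.08, 0.737, 0.475, 0.036),
        (11, 3.06, 0.744, 0.489, 0.034),
        (12, 3.27, 0.765, 0.530, 0.032),
    ],
    UNDULATIFOLIA: [
        (1, 2.71, 0.701, 0.402, 0.055),
        (2, 2.93, 0.723, 0.447, 0.052),
        (3, 2.88, 0.729, 0.457, 0.049),
        (4, 2.70, 0.739, 0.464, 0.048),
        (5, 3.02, 0.744, 0.487, 0.045),
        (6, 3.04, 0.741, 0.481, 0.041),
        (7, 3.00, 0.743, 0.485, 0.039),
        (8, 2.79, 0.723, 0.446, 0.038),
        (9, 3.02, 0.741, 0.482, 0.036),
        (10, 2.63, 0.716, 0.431, 0.034),
        (11, 2.89, 0.732, 0.465, 0.033),
        (12, 2.63, 0.717, 0.434, 0.031),
    ],
}

#: Satellite-bearing pairs consistent with the published karyotype formula of
#: T. scardica (2n = 8 sm + 4 sm-SAT + 2 sm/st-SAT + 10 st). Which pairs carry
#: satellites was not printed; this assignment places them on sm pairs 1-2 and
#: the borderline sm/st pair 8, matching the formula's category counts.
SAT_PAIRS: dict[str, tuple[int, ...]] = {
    SCARDICA: (1, 2, 8),
    UNDULATIFOLIA: (1, 2),
}

KARYOTYPE_FORMULAS = {
    SCARDICA: "8 sm + 4 sm-SAT + 2 sm/st-SAT + 10 st",
    UNDULATIFOLIA: "12 sm + 4 sm-SAT + 6 sm/st + 2 st-SAT",
}

#: Species-level karyomorphometric index summaries: {index: (mean, sd)}.
#: n below is the number of metaphase plates analysed per species.
KARYO_INDEX_SUMMARIES: dict[str, dict[str, tuple[float, float]]] = {
    SCARDICA: {
        "min_length": (8.54, 0.80),
        "max_length": (13.91, 1.91),
        "tcl": (266.07, 27.54),
        "acl": (11.09, 1.15),
        "thl": (133.04, 13.77),
        "cv_cl": (15.92, 1.86),
        "m_ca": (45.73, 2.43),
        "cv_ci": (24.95, 1.16),
    },
    UNDULATIFOLIA: {
        "min_length": (8.53, 0.63),
        "max_length": (15.05, 1.10),
        "tcl": (275.35, 38.58),
        "acl": (11.47, 1.19),
        "thl": (137.67, 13.98),
        "cv_cl": (19.22, 2.22),
        "m_ca": (45.67, 1.89),
        "cv_ci": (23.07, 2.62),
    },
}

KARYO_N_PLATES = {SCARDICA: 10, UNDULATIFOLIA: 36}

#: Quantitative morphological traits, mean +/- SD per species.
#: Units: mixed cm/mm as recorded in the field protocol; ratios dimensionless.
TRAIT_SUMMARIES: dict[str, dict[str, tuple[float, float]]] = {
    SCARDICA: {
        "plant_length": (13.00, 5.41),
        "stem_width": (1.69, 0.22),
        "length_lowest_leaf": (8.73, 1.52),
        "width_lowest_leaf": (1.30, 0.19),
        "length_second_lowest_leaf": (7.86, 1.50),
        "width_second_lowest_leaf": (0.75, 0.15),
        "length_outer_tepal": (3.21, 0.57),
        "width_outer_tepal": (1.55, 0.35),
        "blotch_outer_tepal": (0.77, 0.24),
        "length_inner_tepal": (3.14, 0.49),
        "width_inner_tepal": (1.71, 0.35),
        "blotch_inner_tepal": (0.90, 0.21),
        "length_anther": (4.48, 0.88),
        "width_anther": (1.50, 0.34),
        "length_outer_filament": (4.95, 0.97),
        "length_inner_filament": (4.59, 1.15),
        "ratio_length_width_lowest_leaf": (6.84, 1.41),
        "ratio_length_width_second_lowest_leaf": (10.93, 2.97),
        "ratio_length_width_outer_tepal": (2.13, 0.47),
        "ratio_length_blotch_outer_tepal": (4.39, 1.07),
        "ratio_length_width_inner_tepal": (1.89, 0.37),
        "ratio_length_blotch_inner_tepal": (3.58, 0.61),
        "ratio_outer_inner_tepal_length": (1.02, 0.06),
        "ratio_outer_inner_tepal_width": (0.91, 0.12),
        "ratio_outer_filament_anther": (1.13, 0.25),
        "ratio_inner_filament_anther": (1.04, 0.26),
    },
    UNDULATIFOLIA: {
        "plant_length": (23.86, 5.31),
        "stem_width": (2.32, 0.43),
        "length_lowest_leaf": (17.46, 4.11),
        "width_lowest_leaf": (3.35, 1.04),
        "length_second_lowest_leaf": (16.92, 3.80),
        "width_second_lowest_leaf": (2.18, 0.74),
        "length_outer_tepal": (5.66, 0.82),
        "width_outer_tepal": (2.12, 0.48),
        "blotch_outer_tepal": (1.14, 0.35),
        "length_inner_tepal": (5.45, 0.79),
        "width_inner_tepal": (2.40, 0.48),
        "blotch_inner_tepal": (1.33, 0.34),
        "length_anther": (9.04, 2.51),
        "width_anther": (2.88, 0.55),
        "length_outer_filament": (7.06, 1.69),
        "length_inner_filament": (6.59, 1.61),
        "ratio_length_width_lowest_leaf": (5.49, 1.28),
        "ratio_length_width_second_lowest_leaf": (8.29, 2.16),
        "ratio_length_width_outer_tepal": (2.76, 0.59),
        "ratio_length_blotch_outer_tepal": (5.30, 1.29),
        "ratio_length_width_inner_tepal": (2.33, 0.37),
        "ratio_length_blotch_inner_tepal": (4.25, 0.73),
        "ratio_outer_inner_tepal_length": (1.04, 0.08),
        "ratio_outer_inner_tepal_width": (0.89, 0.13),
        "ratio_outer_filament_anther": (0.84, 0.31),
        "ratio_inner_filament_anther": (0.79, 0.28),
    },
}

#: Units for the measured (non-ratio) traits; ratios are dimensionless.
TRAIT_UNITS: dict[str, str] = {
    "plant_length": "cm",
    "stem_width": "mm",
    "length_lowest_leaf": "cm",
    "width_lowest_leaf": "cm",
    "length_second_lowest_leaf": "cm",
    "width_second_lowest_leaf": "cm",
    "length_outer_tepal": "cm",
    "width_outer_tepal": "cm",
    "blotch_outer_tepal": "cm",
    "length_inner_tepal": "cm",
    "width_inner_tepal": "cm",
    "blotch_inner_tepal": "cm",
    "length_anther": "mm",
    "width_anther": "mm",
    "length_outer_filament": "mm",
    "length_inner_filament": "mm",
    **{
        k: ""
        for k in (
            "ratio_length_width_lowest_leaf",
            "ratio_length_width_second_lowest_leaf",
            "ratio_length_width_outer_tepal",
            "ratio_length_blotch_outer_tepal",
            "ratio_length_width_inner_tepal",
            "ratio_length_blotch_inner_tepal",
            "ratio_outer_inner_tepal_length",
            "ratio_outer_inner_tepal_width",
            "ratio_outer_filament_anther",
            "ratio_inner_filament_anther",
        )
    },
}

#: The eleven traits entering the discriminant analysis.
LDA_TRAITS: tuple[str, ...] = (
    "plant_length",
    "stem_width",
    "ratio_length_width_lowest_leaf",
    "ratio_length_blotch_outer_tepal",
    "ratio_length_width_outer_tepal",
    "ratio_outer_inner_tepal_length",
    "ratio_outer_inner_tepal_width",
    "ratio_length_blotch_inner_tepal",
    "ratio_length_width_inner_tepal",
    "ratio_inner_filament_anther",
    "ratio_outer_filament_anther",
)

#: Field populations with sample sizes (140 individuals total).
POPULATIONS: dict[str, tuple[str, int]] = {
    "Vytouma": (SCARDICA, 25),
    "Fana": (UNDULATIFOLIA, 38),
    "Emporios": (UNDULATIFOLIA, 16),
    "Didima": (UNDULATIFOLIA, 44),
    "Agios_Stefanos": (UNDULATIFOLIA, 17),
}

#: Seed morphometric measurements (mm), mean +/- SD, n = 30 seeds/species.
SEED_SUMMARIES: dict[str, dict[str, tuple[float, float]]] = {
    SCARDICA: {
        "TL": (5.82, 0.44),
        "TW": (4.99, 0.47),
        "EL": (1.85, 0.23),
        "SW": (3.50, 0.38),
        "WW": (1.31, 0.24),
        "SL": (4.42, 0.40),
        "CPL": (2.15, 0.34),
    },
    UNDULATIFOLIA: {
        "TL": (7.79, 0.58),
        "TW": (6.43, 0.52),
        "EL": (2.16, 0.38),
        "SW": (4.75, 0.53),
        "WW": (1.64, 0.28),
        "SL": (5.91, 0.56),
        "CPL": (2.70, 0.29),
    },
}

#: Printed per-seed ratio summaries (mean +/- SD).
SEED_RATIO_SUMMARIES: dict[str, dict[str, tuple[float, float]]] = {
    SCARDICA: {
        "EL_SL": (0.42, 0.05),
        "TL_TW": (1.17, 0.06),
        "SW_WW": (2.74, 0.49),
        "SL_SW": (1.27, 0.11),
        "TL_CPL": (2.75, 0.34),
    },
    UNDULATIFOLIA: {
        "EL_SL": (0.37, 0.08),
        "TL_TW": (1.21, 0.07),
        "SW_WW": (2.99, 0.66),
        "SL_SW": (1.25, 0.11),
        "TL_CPL": (2.90, 0.19),
    },
}

SEED_N = 30
#: Batch mass (g) of the 30-seed lots weighed per species.
SEED_BATCH_MASS = {SCARDICA: 0.1488, UNDULATIFOLIA: 0.1580}

#: Soil properties passthrough table (site-level means +/- SE of 3 replicates);
#: reported verbatim in the evidence summary, no inference is run on it.
SOIL_TABLE: list[dict[str, object]] = [
    {"property": "pH (1:2 H2O)", "T_scardica_Vytouma": "7.4 ± 0.0", "T_undulatifolia_Didima1": "7.7 ± 0.1", "T_undulatifolia_Didima2": "7.5 ± 0.0", "T_undulatifolia_Emporios": "7.8 ± 0.0"},
    {"property": "Organic C (%)", "T_scardica_Vytouma": "1.58 ± 0.18", "T_undulatifolia_Didima1": "1.21 ± 0.07", "T_undulatifolia_Didima2": "1.17 ± 0.04", "T_undulatifolia_Emporios": "0.64 ± 0.03"},
    {"property": "C/N", "T_scardica_Vytouma": "12.1 ± 0.7", "T_undulatifolia_Didima1": "5.9 ± 0.0", "T_undulatifolia_Didima2": "7.1 ± 0.0", "T_undulatifolia_Emporios": "7.4 ± 0.0"},
    {"property": "P (mg/kg)", "T_scardica_Vytouma": "15.0 ± 0.8", "T_undulatifolia_Didima1": "10.9 ± 2.4", "T_undulatifolia_Didima2": "4.2 ± 0.8", "T_undulatifolia_Emporios": "2.2 ± 0.1"},
    {"property": "K (mg/kg)", "T_scardica_Vytouma": "110 ± 16", "T_undulatifolia_Didima1": "593 ± 21", "T_undulatifolia_Didima2": "643 ± 6", "T_undulatifolia_Emporios": "585 ± 7"},
]
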