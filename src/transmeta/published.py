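"""Published summary statistics used as reference inputs.

Per-stratum association results for the SCARB1 intronic variant
rs10846744 (effect allele C vs. reference G, additive coding) from the
Multi-Ethnic Study of Atherosclerosis (MESA) and from the STABILITY and
SOLID-TIMI 52 darapladib trials.  These are the printed per-stratum
(beta, SE) pairs, fixed-effects meta-analysis p-values, trans-ethnic
log10 Bayes factors and heterogeneity statistics for the 27-trait
mediator panel, plus the trials' baseline Lp-PLA2-activity strata.

They serve as worked-example inputs, as regression references for the
meta-analysis routines, and as the input to the carry-forward selection
rule applied to the published screen.
"""

from __future__ import annotations

from .meta import StudyEstimate

MESA_STRATA = ("Caucasian", "African-American", "Hispanic", "Chinese-American")

#: Per-trait published MESA results.  Per-stratum rows are
#: (label, n, beta, se, p); "meta" holds the published fixed-effects
#: combination, trans-ethnic log10 Bayes factor, and Cochran
#: heterogeneity (I2 in percent, het p).
MESA_RS10846744 = {
    "lppla2_mass": {
        "display": 'Lp-PLA_2_ mass, ng/ml',
        "groups": [
            ('Caucasian', 1842, 2.934, 1.665, 0.08),
            ('African-American', 1155, -1.252, 1.728, 0.47),
            ('Hispanic', 1130, 3.224, 1.561, 0.04),
            ('Chinese-American', 602, 1.781, 2.358, 0.45),
        ],
        "meta": {"beta": 1.775, "se": 0.882, "p": 0.04,
                 "log10_bf": 0.3, "i2": 32.0, "het_p": 0.22},
    },
    "lppla2_activity": {
        "display": 'Lp-PLA_2_ activity, nmol/min/ml',
        "groups": [
            ('Caucasian', 1861, 1.541, 1.356, 0.26),
            ('African-American', 1202, 1.469, 1.366, 0.28),
            ('Hispanic', 1155, 3.573, 1.384, 0.01),
            ('Chinese-American', 603, 4.328, 2.206, 0.05),
        ],
        "meta": {"beta": 2.424, "se": 0.744, "p": 0.001,
                 "log10_bf": 1.69, "i2": 0.0, "het_p": 0.5},
    },
    "hscrp": {
        "display": 'hsCRP, mg/L',
        "groups": [
            ('Caucasian', 2452, 0.009, 0.042, 0.84),
            ('African-American', 1949, 0.001, 0.039, 0.99),
            ('Hispanic', 1739, 0.055, 0.039, 0.17),
            ('Chinese-American', 701, 0.022, 0.055, 0.69),
        ],
        "meta": {"beta": 0.022, "se": 0.021, "p": 0.31,
                 "log10_bf": -0.25, "i2": 0.0, "het_p": 0.78},
    },
    "homocysteine": {
        "display": 'Homocysteine, μmol/L',
        "groups": [
            ('Caucasian', 2305, -0.007, 0.01, 0.46),
            ('African-American', 1585, -0.011, 0.01, 0.26),
            ('Hispanic', 1418, -0.014, 0.01, 0.19),
            ('Chinese-American', 703, -0.019, 0.013, 0.16),
        ],
        "meta": {"beta": -0.012, "se": 0.005, "p": 0.03,
                 "log10_bf": 0.69, "i2": 0.0, "het_p": 0.9},
    },
    "il6": {
        "display": 'IL-6, pg/ml',
        "groups": [
            ('Caucasian', 2277, -0.01, 0.025, 0.68),
            ('African-American', 1530, -0.005, 0.025, 0.85),
            ('Hispanic', 1387, 0.007, 0.025, 0.77),
            ('Chinese-American', 695, 0.013, 0.036, 0.73),
        ],
        "meta": {"beta": -0.001, "se": 0.013, "p": 0.97,
                 "log10_bf": -0.8, "i2": 0.0, "het_p": 0.94},
    },
    "eselectin": {
        "display": 'E-selectin, ng/ml',
        "groups": [
            ('Caucasian', 551, -0.482, 1.598, 0.76),
            ('African-American', 223, -0.679, 2.406, 0.78),
            ('Hispanic', 270, -1.478, 2.418, 0.54),
            ('Chinese-American', 93, -0.763, 3.843, 0.84),
        ],
        "meta": {"beta": -0.76, "se": 1.116, "p": 0.5,
                 "log10_bf": -0.4, "i2": 0.0, "het_p": 0.99},
    },
    "pai1": {
        "display": 'PAI-1, ng/ml',
        "groups": [
            ('Caucasian', 398, 0.033, 0.094, 0.73),
            ('African-American', 180, 0.159, 0.095, 0.1),
            ('Hispanic', 216, -0.046, 0.085, 0.59),
            ('Chinese-American', 90, -0.092, 0.116, 0.43),
        ],
        "meta": {"beta": 0.019, "se": 0.048, "p": 0.7,
                 "log10_bf": -0.4, "i2": 18.8, "het_p": 0.3},
    },
    "sicam1": {
        "display": 'sICAM-1, ng/ml',
        "groups": [
            ('Caucasian', 1249, 5.421, 3.252, 0.1),
            ('African-American', 452, -6.193, 6.483, 0.34),
            ('Hispanic', 600, -3.829, 4.686, 0.41),
            ('Chinese-American', 260, -3.125, 5.187, 0.55),
        ],
        "meta": {"beta": -0.371, "se": 2.23, "p": 0.87,
                 "log10_bf": -0.35, "i2": 36.1, "het_p": 0.2},
    },
    "ldl_particle_number": {
        "display": 'LDL particle number, nmol/L',
        "groups": [
            ('Caucasian', 2311, 8.388, 12.148, 0.49),
            ('African-American', 1585, 9.345, 12.942, 0.47),
            ('Hispanic', 1418, 41.361, 13.901, 0.003),
            ('Chinese-American', 705, 12.628, 17.364, 0.47),
        ],
        "meta": {"beta": 17.354, "se": 6.862, "p": 0.01,
                 "log10_bf": 1.16, "i2": 24.7, "het_p": 0.26},
    },
    "ala": {
        "display": 'ALA, %',
        "groups": [
            ('Caucasian', 2247, 0.034, 0.013, 0.01),
            ('African-American', 1525, 0.008, 0.013, 0.56),
            ('Hispanic', 1373, -0.008, 0.015, 0.58),
            ('Chinese-American', 698, 0.014, 0.021, 0.49),
        ],
        "meta": {"beta": 0.013, "se": 0.007, "p": 0.08,
                 "log10_bf": 0.23, "i2": 36.4, "het_p": 0.19},
    },
    "epa": {
        "display": 'EPA, %',
        "groups": [
            ('Caucasian', 1600, 0.041, 0.025, 0.09),
            ('African-American', 891, 0.009, 0.027, 0.74),
            ('Hispanic', 692, 0.002, 0.029, 0.94),
            ('Chinese-American', 51, -0.097, 0.147, 0.51),
        ],
        "meta": {"beta": 0.019, "se": 0.015, "p": 0.23,
                 "log10_bf": -0.14, "i2": 0.0, "het_p": 0.6},
    },
    "dha": {
        "display": 'DHA, %',
        "groups": [
            ('Caucasian', 2247, 0.088, 0.045, 0.05),
            ('African-American', 1522, 0.039, 0.049, 0.42),
            ('Hispanic', 1369, 0.051, 0.042, 0.23),
            ('Chinese-American', 696, 0.091, 0.078, 0.24),
        ],
        "meta": {"beta": 0.063, "se": 0.025, "p": 0.01,
                 "log10_bf": 0.86, "i2": 0.0, "het_p": 0.86},
    },
    "dpa": {
        "display": 'DPA. %',
        "groups": [
            ('Caucasian', 2244, 0.0, 0.008, 0.97),
            ('African-American', 1521, 0.018, 0.008, 0.03),
            ('Hispanic', 1370, 0.009, 0.008, 0.29),
            ('Chinese-American', 694, 0.011, 0.013, 0.43),
        ],
        "meta": {"beta": 0.009, "se": 0.004, "p": 0.04,
                 "log10_bf": 0.53, "i2": 0.0, "het_p": 0.47},
    },
    "la": {
        "display": 'LA, %',
        "groups": [
            ('Caucasian', 2254, -0.049, 0.113, 0.67),
            ('African-American', 1530, -0.084, 0.105, 0.42),
            ('Hispanic', 1376, -0.129, 0.121, 0.29),
            ('Chinese-American', 697, -0.29, 0.191, 0.13),
        ],
        "meta": {"beta": -0.107, "se": 0.062, "p": 0.08,
                 "log10_bf": 0.24, "i2": 0.0, "het_p": 0.74},
    },
    "gla": {
        "display": 'GLA, %',
        "groups": [
            ('Caucasian', 2238, 0.0, 0.002, 0.98),
            ('African-American', 1525, 0.003, 0.002, 0.1),
            ('Hispanic', 1368, 0.0, 0.002, 0.82),
            ('Chinese-American', 691, 0.003, 0.003, 0.35),
        ],
        "meta": {"beta": 0.001, "se": 0.001, "p": 0.24,
                 "log10_bf": -0.35, "i2": 0.0, "het_p": 0.6},
    },
    "dgla": {
        "display": 'DGLA, %',
        "groups": [
            ('Caucasian', 2252, -0.01, 0.031, 0.75),
            ('African-American', 1526, 0.004, 0.025, 0.88),
            ('Hispanic', 1377, 0.031, 0.035, 0.38),
            ('Chinese-American', 699, 0.051, 0.044, 0.24),
        ],
        "meta": {"beta": 0.012, "se": 0.016, "p": 0.45,
                 "log10_bf": -0.46, "i2": 0.0, "het_p": 0.64},
    },
    "aa": {
        "display": 'AA, %',
        "groups": [
            ('Caucasian', 2255, -0.041, 0.089, 0.64),
            ('African-American', 1527, -0.071, 0.089, 0.43),
            ('Hispanic', 1375, 0.105, 0.096, 0.28),
            ('Chinese-American', 698, -0.007, 0.118, 0.95),
        ],
        "meta": {"beta": -0.008, "se": 0.048, "p": 0.88,
                 "log10_bf": -0.5, "i2": 0.0, "het_p": 0.57},
    },
    "aa_la": {
        "display": 'AA/LA',
        "groups": [
            ('Caucasian', 2246, 0.0, 0.006, 0.1),
            ('African-American', 1524, 0.0, 0.007, 0.97),
            ('Hispanic', 1369, 0.012, 0.007, 0.06),
            ('Chinese-American', 696, 0.005, 0.008, 0.48),
        ],
        "meta": {"beta": 0.004, "se": 0.003, "p": 0.2,
                 "log10_bf": -0.19, "i2": 0.0, "het_p": 0.55},
    },
    "gla_la": {
        "display": 'GLA/LA',
        "groups": [
            ('Caucasian', 2244, 0.0, 0.001, 0.81),
            ('African-American', 1524, 0.001, 0.001, 0.08),
            ('Hispanic', 1372, 0.0, 0.001, 0.64),
            ('Chinese-American', 696, 0.0, 0.001, 0.65),
        ],
        "meta": {"beta": 0.001, "se": 0.0, "p": 0.12,
                 "log10_bf": -0.54, "i2": 0.0, "het_p": 0.86},
    },
    "dgla_gla": {
        "display": 'DGLA/GLA',
        "groups": [
            ('Caucasian', 2250, -0.011, 0.016, 0.51),
            ('African-American', 1525, -0.025, 0.015, 0.09),
            ('Hispanic', 1374, 0.008, 0.017, 0.63),
            ('Chinese-American', 698, 0.009, 0.025, 0.73),
        ],
        "meta": {"beta": -0.009, "se": 0.009, "p": 0.33,
                 "log10_bf": -0.28, "i2": 0.0, "het_p": 0.45},
    },
    "aa_dgla": {
        "display": 'AA/DGLA',
        "groups": [
            ('Caucasian', 2251, -0.002, 0.012, 0.86),
            ('African-American', 1527, -0.008, 0.012, 0.51),
            ('Hispanic', 1373, 0.005, 0.012, 0.7),
            ('Chinese-American', 697, -0.02, 0.019, 0.29),
        ],
        "meta": {"beta": -0.004, "se": 0.007, "p": 0.54,
                 "log10_bf": -1.09, "i2": 0.0, "het_p": 0.7},
    },
    "dgla_la": {
        "display": 'DGLA/LA',
        "groups": [
            ('Caucasian', 2248, 0.0, 0.002, 0.94),
            ('African-American', 1525, 0.001, 0.002, 0.46),
            ('Hispanic', 1371, 0.002, 0.002, 0.35),
            ('Chinese-American', 697, 0.004, 0.002, 0.1),
        ],
        "meta": {"beta": 0.002, "se": 0.001, "p": 0.11,
                 "log10_bf": 0.22, "i2": 0.0, "het_p": 0.53},
    },
    "dha_ala": {
        "display": 'DHA/ALA',
        "groups": [
            ('Caucasian', 2250, -0.01, 0.018, 0.58),
            ('African-American', 1529, 0.001, 0.018, 0.95),
            ('Hispanic', 1375, 0.025, 0.021, 0.23),
            ('Chinese-American', 698, -0.011, 0.027, 0.69),
        ],
        "meta": {"beta": -0.002, "se": 0.01, "p": 0.87,
                 "log10_bf": -0.4, "i2": 0.0, "het_p": 0.6},
    },
    "epa_ala": {
        "display": 'EPA/ALA',
        "groups": [
            ('Caucasian', 2248, -0.002, 0.022, 0.94),
            ('African-American', 1525, 0.025, 0.023, 0.27),
            ('Hispanic', 1370, 0.032, 0.023, 0.16),
            ('Chinese-American', 697, 0.044, 0.042, 0.3),
        ],
        "meta": {"beta": 0.02, "se": 0.012, "p": 0.1,
                 "log10_bf": -0.54, "i2": 0.0, "het_p": 0.65},
    },
    "dpa_epa": {
        "display": 'DPA/EPA',
        "groups": [
            ('Caucasian', 2248, -0.02, 0.009, 0.03),
            ('African-American', 1527, -0.012, 0.01, 0.2),
            ('Hispanic', 1376, -0.01, 0.01, 0.33),
            ('Chinese-American', 697, -0.025, 0.015, 0.11),
        ],
        "meta": {"beta": -0.016, "se": 0.005, "p": 0.002,
                 "log10_bf": 1.52, "i2": 0.0, "het_p": 0.78},
    },
    "dha_epa": {
        "display": 'DHA/EPA',
        "groups": [
            ('Caucasian', 2248, -0.024, 0.017, 0.17),
            ('African-American', 1526, -0.03, 0.019, 0.12),
            ('Hispanic', 1374, -0.022, 0.022, 0.31),
            ('Chinese-American', 696, -0.051, 0.034, 0.148),
        ],
        "meta": {"beta": -0.028, "se": 0.011, "p": 0.008,
                 "log10_bf": 1.09, "i2": 0.0, "het_p": 0.9},
    },
    "dha_dpa": {
        "display": 'DHA/DPA',
        "groups": [
            ('Caucasian', 2253, 0.023, 0.012, 0.06),
            ('African-American', 1526, -0.009, 0.012, 0.43),
            ('Hispanic', 1376, 0.004, 0.013, 0.77),
            ('Chinese-American', 697, -0.001, 0.015, 0.92),
        ],
        "meta": {"beta": 0.004, "se": 0.006, "p": 0.52,
                 "log10_bf": -0.5, "i2": 20.6, "het_p": 0.29},
    },
}

#: Baseline Lp-PLA2 activity per-stratum rows from the darapladib trials:
#: (label, effect-allele frequency, n, beta, se, p).  The published
#: random-effects (DerSimonian-Laird) combinations are 3.82 (0.59) for
#: STABILITY and 2.209 (1.16) for SOLID-TIMI 52.
STABILITY_ACTIVITY = [
    ('Caucasian', 0.17, 9448, 4.15, 0.67, 5.52e-10),
    ('African-American', 0.53, 254, 4.78, 4.12, 0.247),
    ('Asian', 0.64, 1257, 3.18, 2.06, 0.122),
    ('Other', 0.25, 1637, 2.1, 1.63, 0.196),
]

SOLID_ACTIVITY = [
    ('Caucasian', 0.16, 7503, 3.305, 0.76, 1.51e-05),
    ('African-American', 0.59, 185, 5.823, 4.44, 0.191),
    ('Asian', 0.62, 408, -2.661, 3.51, 0.449),
    ('Other', 0.27, 1303, 0.977, 1.63, 0.55),
]


def study_estimates(trait: str) -> list[StudyEstimate]:
    """Published per-stratum rows for ``trait`` as StudyEstimate objects."""
    rows = MESA_RS10846744[trait]["groups"]
    return [StudyEstimate(label=r[0], beta=r[2], se=r[3], n=r[1]) for r in rows]


def trial_estimates(rows) -> list[StudyEstimate]:
    """Trial baseline-biomarker rows as StudyEstimate objects."""
    return [StudyEstimate(label=r[0], beta=r[3], se=r[4], n=r[2]) for r in rows]
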