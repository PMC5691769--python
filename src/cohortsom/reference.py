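"""Published summary statistics bundled as the default simulation scenario.

The source cohort was never deposited, so the generator targets the printed
subgroup profile table instead: per-subgroup trait means with 95% confidence
intervals, subgroup sizes, and the headline participant counts of the study
design. Standard deviations are recovered from the CI half-widths via
``sd = half_width * sqrt(n) / 1.96``.

Trait keys ending in ``_pct`` are percentages of the subgroup; all other
traits are per-participant means (units noted below).

Units: age years; bmi kg/m^2; hemoglobin g/L; ferritin ng/mL;
total_calories kcal/day; food intakes g/day; iron mg/day; fibre g/day;
income Yuan/person.
"""

from __future__ import annotations

import math

#: Headline participant counts of the study design.
STUDY_COUNTS = {
    "baseline_total": 2849,
    "baseline_cases": 725,
    "baseline_controls": 1801,
    "at_risk_followed": 876,
    "incident_cases": 167,
    "prospective_controls": 650,
    "training_set": 968,
    "lost_to_followup": 1587,
    "followed_up": 1262,
    "followup_years": 5,
}

#: Whole-evaluation-set means used as the reference column of summaries.
EVALUATION_MEANS = {
    "southern_pct": 66.0,
    "incident_anemia_pct": 19.0,
    "female_pct": 54.0,
    "age": 49.0,
    "bmi": 24.0,
    "hemoglobin": 140.0,
    "ferritin": 102.0,
    "total_calories": 2378.0,
    "rice": 272.0,
    "wheat": 105.0,
    "total_meat": 151.0,
    "total_vegetable": 366.0,
    "legumes": 15.0,
    "fibre": 12.0,
    "soy_sauce": 11.0,
    "iron": 26.0,
    "low_iron_pct": 12.0,
    "urban_pct": 15.0,
    "low_education_pct": 51.0,
    "income": 3405.0,
}

#: Per-subgroup trait profiles: ``trait -> (mean, ci_low, ci_high)``.
SUBGROUP_PROFILES = {
    "I": {
        "label": "high_fibre",
        "n": 143,
        "traits": {
            "southern_pct": (3, 1, 7),
            "incident_anemia_pct": (10, 6, 16),
            "female_pct": (59, 52, 67),
            "age": (46, 44, 48),
            "bmi": (23, 23, 24),
            "hemoglobin": (143, 141, 145),
            "ferritin": (73, 63, 84),
            "total_calories": (2760, 2656, 2869),
            "rice": (137, 117, 158),
            "wheat": (277, 246, 308),
            "total_meat": (61, 49, 74),
            "total_vegetable": (434, 392, 479),
            "legumes": (24, 20, 30),
            "fibre": (27, 24, 29),
            "soy_sauce": (17, 13, 22),
            "iron": (35, 33, 36),
            "low_iron_pct": (0, 0, 0),
            "urban_pct": (4, 1, 8),
            "low_education_pct": (65, 57, 73),
            "income": (1542, 1364, 1731),
        },
    },
    "II": {
        "label": "low_vegetable",
        "n": 160,
        "traits": {
            "southern_pct": (34, 27, 42),
            "incident_anemia_pct": (25, 19, 32),
            "female_pct": (48, 41, 56),
            "age": (52, 50, 54),
            "bmi": (24, 24, 25),
            "hemoglobin": (141, 139, 143),
            "ferritin": (106, 92, 119),
            "total_calories": (1988, 1918, 2061),
            "rice": (193, 174, 212),
            "wheat": (157, 137, 178),
            "total_meat": (94, 81, 107),
            "total_vegetable": (286, 265, 309),
            "legumes": (13, 10, 16),
            "fibre": (11, 10, 11),
            "soy_sauce": (8, 7, 10),
            "iron": (21, 20, 22),
            "low_iron_pct": (15, 10, 21),
            "urban_pct": (24, 18, 31),
            "low_education_pct": (62, 54, 69),
            "income": (2741, 2484, 2994),
        },
    },
    "III": {
        "label": "low_fibre",
        "n": 250,
        "traits": {
            "southern_pct": (98, 96, 100),
            "incident_anemia_pct": (10, 7, 14),
            "female_pct": (59, 52, 65),
            "age": (50, 48, 52),
            "bmi": (24, 23, 24),
            "hemoglobin": (139, 137, 141),
            "ferritin": (110, 100, 121),
            "total_calories": (1954, 1901, 2007),
            "rice": (271, 260, 282),
            "wheat": (46, 38, 53),
            "total_meat": (177, 165, 188),
            "total_vegetable": (307, 294, 320),
            "legumes": (13, 11, 15),
            "fibre": (7, 7, 8),
            "soy_sauce": (8, 7, 9),
            "iron": (20, 20, 21),
            "low_iron_pct": (22, 17, 27),
            "urban_pct": (26, 21, 32),
            "low_education_pct": (42, 36, 48),
            "income": (4154, 3992, 4310),
        },
    },
    "IV": {
        "label": "high_rice",
        "n": 323,
        "traits": {
            "southern_pct": (83, 79, 87),
            "incident_anemia_pct": (27, 22, 31),
            "female_pct": (51, 46, 57),
            "age": (47, 46, 48),
            "bmi": (24, 23, 24),
            "hemoglobin": (139, 138, 141),
            "ferritin": (107, 98, 117),
            "total_calories": (2733, 2670, 2797),
            "rice": (372, 360, 385),
            "wheat": (49, 40, 59),
            "total_meat": (198, 185, 211),
            "total_vegetable": (422, 404, 440),
            "legumes": (14, 11, 16),
            "fibre": (11, 10, 12),
            "soy_sauce": (11, 10, 13),
            "iron": (28, 27, 29),
            "low_iron_pct": (8, 6, 11),
            "urban_pct": (6, 3, 9),
            "low_education_pct": (46, 40, 51),
            "income": (3984, 3847, 4115),
        },
    },
}

SUBGROUP_ORDER = ("I", "II", "III", "IV")


def sd_from_ci(low: float, high: float, n: int) -> float:
    """Invert a 95% CI of a mean into a sample standard deviation.

    ``sd = (high - low) / 2 * sqrt(n) / 1.96``
    """
    return (high - low) / 2.0 * math.sqrt(n) / 1.96


def subgroup_mean(subgroup: str, trait: str) -> float:
    """Printed mean of ``trait`` in ``subgroup``."""
    return float(SUBGROUP_PROFILES[subgroup]["traits"][trait][0])


def subgroup_sd(subgroup: str, trait: str) -> float:
    """Standard deviation of ``trait`` recovered from the printed CI."""
    mean, low, high = SUBGROUP_PROFILES[subgroup]["traits"][trait]
    return sd_from_ci(low, high, SUBGROUP_PROFILES[subgroup]["n"])
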