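"""Bundled reference dataset: a five-diet buffalo feeding trial.

Three rumen-fistulated buffaloes were fed diets with concentrate:roughage
ratios 20:80, 35:65, 50:50, 65:35 and 80:20 (an incomplete 3x5 Latin
square). The tables here transcribe the trial's group-level summaries:
diet nutrient composition (% of DM), rumen VFA concentrations (mmol/L),
the acetate proportion of total VFA, the Spirochaetes relative-abundance
series, Prevotella 1 group means, per-nutrient apparent digestibility, and
the trend equations reported for the core phyla along the concentrate
gradient. They serve as worked inputs for the fitting and crossover
machinery and as generating truths for the synthetic-trial module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import DietSpec, NutrientProfile, StandardCurve

__all__ = [
    "GROUP_LABELS",
    "CONCENTRATE_FRACTIONS",
    "DIET_NUTRIENTS",
    "VFA_MMOL",
    "ACETATE_PROPORTION",
    "SPIROCHAETES_ABUNDANCE",
    "PREVOTELLA1_ABUNDANCE",
    "DIGESTIBILITY_PCT",
    "NH3N_STANDARD_CURVE",
    "BACTEROIDETES_LINE",
    "FIRMICUTES_LINE",
    "SPIROCHAETES_EXP",
    "NH3N_CP_LINE",
    "ACETATE_NDF_LINE",
    "ACETATE_NFC_LINE",
    "reference_diets",
]

GROUP_LABELS = ("20:80", "35:65", "50:50", "65:35", "80:20")
CONCENTRATE_FRACTIONS = (0.20, 0.35, 0.50, 0.65, 0.80)

# Diet nutrient composition, % of DM (GE in cal/g), one column per group.
DIET_NUTRIENTS = pd.DataFrame(
    {
        "20:80": [48.10, 91.02, 9.69, 1.95, 8.98, 0.60, 0.23, 51.71, 35.67,
                  4.13, 1.44, 0.78, 29.11, 50.27, 14.76, 3735.97],
        "35:65": [53.26, 91.21, 12.15, 2.01, 8.79, 0.72, 0.28, 44.84, 30.65,
                  3.53, 1.60, 0.80, 33.81, 43.25, 20.41, 3765.74],
        "50:50": [58.09, 91.58, 14.89, 2.10, 8.42, 0.85, 0.33, 36.9233, 24.83,
                  2.86, 1.76, 0.82, 39.43, 35.16, 26.06, 3795.52],
        "65:35": [65.53, 91.83, 17.52, 2.17, 8.17, 0.98, 0.38, 29.50, 19.39,
                  2.23, 1.93, 0.84, 44.57, 27.57, 31.71, 3825.29],
        "80:20": [73.70, 92.12, 20.07, 2.26, 7.88, 1.10, 0.43, 22.21, 14.04,
                  1.61, 2.09, 0.86, 49.68, 20.12, 37.36, 3855.06],
    },
    index=["dm", "om", "cp", "ee", "ash", "ca", "p", "ndf", "adf", "adl",
           "ndicp", "adicp", "nfc", "ndfn", "starch", "ge"],
)

# Rumen VFA concentrations (mmol/L), group means.
VFA_MMOL = pd.DataFrame(
    {
        "20:80": [73.58, 19.36, 0.76, 8.77, 0.58, 1.20, 0.38],
        "35:65": [84.79, 21.15, 0.96, 10.58, 0.76, 1.42, 0.50],
        "50:50": [67.28, 16.86, 0.87, 9.98, 0.76, 1.36, 0.51],
        "65:35": [73.42, 18.46, 1.11, 13.26, 1.07, 1.58, 0.59],
        "80:20": [76.57, 20.44, 1.20, 13.54, 1.28, 1.91, 0.58],
    },
    index=["acetic", "propionic", "isobutyric", "butyric", "isovaleric",
           "pentanoic", "caproic"],
)

#: group-mean proportion of acetic acid in total VFA
ACETATE_PROPORTION = pd.Series(
    [0.70, 0.70, 0.69, 0.67, 0.67], index=list(GROUP_LABELS)
)

#: Spirochaetes relative abundance per group (as proportions)
SPIROCHAETES_ABUNDANCE = pd.Series(
    [0.0024, 0.0029, 0.0033, 0.0045, 0.0435], index=list(GROUP_LABELS)
)

#: Prevotella 1 relative abundance per group (as proportions)
PREVOTELLA1_ABUNDANCE = pd.Series(
    [0.4415, 0.3937, 0.2127, 0.14, 0.0789], index=list(GROUP_LABELS)
)

# Apparent digestibility (%), group means from the total-collection trial.
DIGESTIBILITY_PCT = pd.DataFrame(
    {
        "20:80": [53.19, 69.17, 80.68, 39.62, 45.44, 23.88, 34.27, 16.41,
                  7.51, 56.82, 45.75, 19.74, 14.65, 69.76],
        "35:65": [63.11, 71.84, 75.62, 47.11, 64.17, 38.46, 39.38, 23.10,
                  16.73, 66.97, 65.09, 26.56, 12.46, 67.03],
        "50:50": [64.32, 76.10, 81.66, 41.23, 49.15, 30.74, 38.11, 19.85,
                  9.97, 68.41, 49.69, 12.38, 20.00, 81.38],
        "65:35": [73.11, 75.50, 71.91, 43.12, 50.89, 30.44, 33.78, 36.19,
                  7.93, 76.39, 52.09, 27.21, 15.39, 91.74],
        "80:20": [74.78, 76.06, 73.05, 38.95, 46.65, 24.62, 44.96, 30.93,
                  14.51, 78.53, 46.83, 17.40, 30.27, 93.60],
    },
    index=["dm", "cp", "ee", "adf", "ndf", "adicp", "ndicp", "ash", "adl",
           "om", "ndfn", "ca", "p", "nfc"],
)

#: NH4Cl colorimetric standard curve: absorbance = 0.0423*(mg/dL) + 0.0157
NH3N_STANDARD_CURVE = StandardCurve(slope=0.0423, intercept=0.0157, r2=0.9985)

# Reported trend equations along the concentrate fraction x in [0, 1]:
#   relative abundance of Bacteroidetes = -0.4605 x + 0.8335  (R^2 0.9582)
#   relative abundance of Firmicutes    =  0.4233 x + 0.152   (R^2 0.959)
#   relative abundance of Spirochaetes  =  0.0007 e^(4.156 x) (R^2 as reported 0.8175)
BACTEROIDETES_LINE = (-0.4605, 0.8335)  # (slope, intercept)
FIRMICUTES_LINE = (0.4233, 0.152)
SPIROCHAETES_EXP = (0.0007, 4.156)  # (prefactor a, rate k)

#: rumen NH3-N (mg/dL) vs dietary crude protein (% DM): 2.0426*CP - 8.4155
NH3N_CP_LINE = (2.0426, -8.4155)
#: acetate proportion of TVFA vs dietary NDF (% DM)
ACETATE_NDF_LINE = (0.0012, 0.641)
#: acetate proportion of TVFA vs dietary NFC (% DM)
ACETATE_NFC_LINE = (-0.0017, 0.7545)


def reference_diets() -> list[DietSpec]:
    """The five trial diets as DietSpec objects."""
    diets = []
    for label, frac in zip(GROUP_LABELS, CONCENTRATE_FRACTIONS):
        col = DIET_NUTRIENTS[label]
        diets.append(
            DietSpec(
                group_label=label,
                concentrate_fraction=frac,
                profile=NutrientProfile(**col.to_dict()),
            )
        )
    return diets
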