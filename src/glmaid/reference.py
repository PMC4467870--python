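"""Reference summary of the original 167-sample Tenerife tomato cohort.

The raw sample-level data behind the original study were never deposited;
what is available is a per-parameter summary: mean content (fresh-weight
units), standard deviation, the factorial-GLM terms that reached
significance (with their printed p-values), and the model's explained
variance.  That summary is the single calibration target of the synthetic
cohort generator (:mod:`glmaid.cohort`) and the input of the
predictor-selection worked example.

Factors and levels
------------------
cultivar   : Dorothy, Boludo, Dominique, Thomas, Dunkan
practice   : conventional, organic, no-soil
harvest    : October, December, February, April

Model terms are labelled ``c`` (cultivar), ``p`` (practice), ``h``
(harvest) and their interactions ``c:p``, ``c:h``, ``p:h``, ``c:p:h``.
A printed p-value of 0.000 is stored as 0.0.
"""

from __future__ import annotations

import pandas as pd

FACTORS = ("cultivar", "practice", "harvest")

CULTIVARS = ("Dorothy", "Boludo", "Dominique", "Thomas", "Dunkan")
PRACTICES = ("conventional", "organic", "no-soil")
HARVESTS = ("October", "December", "February", "April")

LEVELS = {"cultivar": CULTIVARS, "practice": PRACTICES, "harvest": HARVESTS}

#: The seven non-baseline, non-error terms of the three-way factorial GLM.
TERMS = ("c", "p", "h", "c:p", "c:h", "p:h", "c:p:h")

#: Which factors each term involves.
TERM_FACTORS = {
    "c": ("cultivar",),
    "p": ("practice",),
    "h": ("harvest",),
    "c:p": ("cultivar", "practice"),
    "c:h": ("cultivar", "harvest"),
    "p:h": ("practice", "harvest"),
    "c:p:h": ("cultivar", "practice", "harvest"),
}

MAIN_EFFECTS = ("c", "p", "h")

FACTOR_OF_MAIN = {"c": "cultivar", "p": "practice", "h": "harvest"}

TOTAL_SAMPLES = 167
TRAINING_SAMPLES = 151
VALIDATION_SAMPLES = 16

# (name, unit, mean, sd, {term: printed p-value}, explained variance %)
_ROWS = [
    ("Fructose", "%", 1.28, 0.41,
     {"h": 0.012, "p": 0.001, "c:p:h": 0.030}, 47.6),
    ("Glucose", "%", 1.29, 0.41,
     {"h": 0.0, "p": 0.0, "c:h": 0.004, "c:p": 0.033}, 56.7),
    ("Total fiber", "%", 1.81, 0.56,
     {"h": 0.006, "p": 0.008, "c:h": 0.001, "c:p": 0.027,
      "p:h": 0.0, "c:p:h": 0.003}, 57.3),
    ("Protein", "%", 0.80, 0.15,
     {"h": 0.005, "p": 0.018}, 36.2),
    ("Phenolic compounds", "mg/100g", 20.41, 4.37,
     {"h": 0.020, "c:h": 0.005}, 38.3),
    ("Lycopene", "mg/100g", 2.31, 0.72,
     {"h": 0.0}, 53.9),
    ("P", "mg/kg", 246.0, 61.0,
     {"p": 0.0, "c:p:h": 0.034}, 50.3),
    ("Na", "mg/kg", 92.4, 63.4,
     {"c": 0.004, "p": 0.0, "c:p": 0.004, "p:h": 0.018}, 58.8),
    ("K", "mg/kg", 2522.0, 512.0,
     {"h": 0.0, "p": 0.015}, 52.2),
    ("Ca", "mg/kg", 67.5, 18.6,
     {"c": 0.010, "h": 0.001, "p": 0.0, "c:h": 0.002,
      "c:p": 0.0, "p:h": 0.009}, 59.3),
    ("Mg", "mg/kg", 115.0, 22.0,
     {"h": 0.0, "p": 0.0, "c:p:h": 0.038}, 59.3),
    ("Fe", "mg/kg", 1.92, 0.05,
     {"c": 0.0, "h": 0.020, "c:h": 0.040, "c:p": 0.002, "p:h": 0.0}, 53.3),
    ("Cu", "mg/kg", 0.30, 0.15,
     {"h": 0.0, "p": 0.022, "c:h": 0.017}, 50.4),
    ("Zn", "mg/kg", 0.77, 0.21,
     {"h": 0.045, "p": 0.0, "c:p": 0.024}, 49.9),
    ("Mn", "mg/kg", 0.60, 0.21,
     {"c": 0.0, "h": 0.008, "p": 0.0, "c:p": 0.0, "p:h": 0.032}, 69.8),
    ("Ascorbic acid", "mg/100g", 15.3, 4.48,
     {"c:p": 0.035}, 37.8),
    ("Oxalic acid", "mg/100g", 25.6, 9.3,
     {"p": 0.011}, 37.5),
    ("Pyruvic acid", "mg/100g", 1.37, 0.77,
     {"c": 0.031, "h": 0.001, "c:h": 0.0, "c:p": 0.028, "c:p:h": 0.004},
     59.8),
    ("Malic acid", "mg/100g", 78.3, 40.2,
     {"c": 0.0, "h": 0.0, "p": 0.0, "c:h": 0.001, "c:p": 0.0,
      "p:h": 0.002, "c:p:h": 0.0}, 75.0),
    ("Citric acid", "mg/100g", 354.0, 121.0,
     {"h": 0.0, "p": 0.043, "c:h": 0.037, "c:p": 0.013}, 48.2),
    ("Fumaric acid", "mg/100g", 2.77, 1.22,
     {"h": 0.009}, 36.0),
    ("Chlorogenic acid", "mg/100g", 0.59, 0.05,
     {"h": 0.0, "c:h": 0.027, "p:h": 0.030}, 50.7),
    ("Caffeic acid", "mg/100g", 0.04, 0.01,
     {"h": 0.0}, 53.9),
    ("Ferulic acid", "mg/100g", 0.09, 0.04,
     {"c": 0.032, "h": 0.0, "c:p": 0.001, "p:h": 0.022}, 57.2),
    ("p-Coumaric acid", "mg/100g", 0.02, 0.03,
     {"h": 0.0}, 73.6),
]

#: Canonical parameter order (ties in rankings are broken by this order).
PARAMETER_NAMES = tuple(r[0] for r in _ROWS)

PARAMETER_UNITS = {r[0]: r[1] for r in _ROWS}

#: Per-harvest mean p-coumaric acid content reported for the original
#: cohort (mg/100 g); April is a non-detect recorded as 0.
P_COUMARIC_HARVEST_MEANS = {
    "October": 0.52, "December": 0.17, "February": 0.02, "April": 0.0,
}

#: The ten inputs retained after weight-sum importance reduction in the
#: original study; used by the reduced (10-input) authentication networks.
REDUCED_INPUTS = (
    "Glucose", "Lycopene", "P", "Na", "K", "Mg", "Fe",
    "Chlorogenic acid", "Caffeic acid", "p-Coumaric acid",
)


def reference_summary() -> pd.DataFrame:
    """Published per-parameter summary as a tidy DataFrame.

    One row per chemical parameter, columns ``mean``, ``sd``, one column
    per GLM term holding the printed p-value (NaN where the term was not
    significant and therefore not printed), and ``explained_variance``.
    """
    records = []
    for name, unit, mean, sd, pvals, ev in _ROWS:
        rec = {"parameter": name, "unit": unit, "mean": mean, "sd": sd,
               "explained_variance": ev}
        for term in TERMS:
            rec[term] = pvals.get(term, float("nan"))
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("parameter")


def significant_terms(name: str) -> dict[str, float]:
    """Terms printed as significant for ``name``, with their p-values."""
    for row in _ROWS:
        if row[0] == name:
            return dict(row[4])
    raise KeyError(f"unknown parameter: {name!r}")
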