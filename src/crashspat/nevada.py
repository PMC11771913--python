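"""Published Nevada older-driver crash summary (NDOT registry, 2014-2017).

The underlying crash registry is not public; what is public is its printed
summary: statewide and per-county crash totals, the binary severity split
(property-damage-only vs injury/fatality) for older drivers (age >= 65) in
Clark County and Washoe, and the marginal category proportions of each coded
covariate.  Those numbers serve two roles here:

* worked-example arithmetic (severity shares, county totals) that can be
  recomputed exactly from the printed counts, and
* the default category structure and proportions of the synthetic crash
  generator, so simulated tables mirror the real data's coding.

Category codes follow the registry convention that code 0 is the
"Unknown"/"Other" bucket.  Proportions below are the printed Clark County
percentages normalized to sum to 1 (the printed raw counts for one variable
are internally inconsistent with the column total, the percentages are not).
"""

from __future__ import annotations

import numpy as np

#: Statewide crash total, 2014-2017.
STATE_TOTAL_CRASHES = 146_751

#: All-age crash totals for the two most crash-burdened counties.
COUNTY_CRASHES = {"clark": 108_306, "washoe": 23_415}

#: Older-driver (>= 65) crash counts by binary severity outcome.
SEVERITY_COUNTS = {
    "clark": {"pdo": 2420, "injury_fatality": 4250},
    "washoe": {"pdo": 565, "injury_fatality": 1075},
}

#: Printed Clark County category percentages per coded covariate,
#: ordered by code 0, 1, 2, ...
CATEGORY_PERCENTAGES: dict[str, list[float]] = {
    "crash_type":          [0.07, 42.94, 0.40, 1.23, 29.97, 3.61, 21.77],
    "vehicle1_type":       [8.79, 54.54, 14.68, 18.20, 3.79],
    "vehicle1_action":     [4.54, 0.49, 3.25, 57.08, 1.65, 0.45, 0.63,
                            18.16, 5.07, 1.21, 7.47],
    "vehicle1_driver_condition": [13.67, 61.66, 14.24, 1.68, 0.96, 4.56,
                                  0.36, 2.86],
    "vehicle1_condition":  [7.43, 8.96, 2.59, 34.64, 6.33, 10.89, 1.45,
                            3.81, 8.41, 6.72, 8.73],
    "vehicle2_type":       [2.89, 42.64, 12.11, 17.93, 24.42],
    "vehicle2_driver_age": [4.51, 27.47, 14.80, 45.53, 7.69],
    "vehicle2_action":     [23.63, 0.06, 0.45, 45.41, 0.16, 0.06, 23.75,
                            4.74, 1.12, 0.12, 0.49],
    "vehicle2_driver_condition": [26.33, 72.50, 0.76, 0.28, 0.01, 0.01,
                                  0.00, 0.09],
    "vehicle2_condition":  [7.44, 8.97, 2.58, 34.63, 6.34, 10.90, 1.44,
                            3.80, 8.42, 6.73, 8.72],
    "road_condition":      [0.25, 95.85, 3.78, 0.12],
    "weather":             [0.04, 99.15, 0.39, 0.04, 0.37],
    "lighting":            [0.03, 36.61, 60.61, 2.74],
}

#: Total vehicles involved: printed mean and standard deviation (Clark).
TOTAL_VEHICLES_MEAN = 1.98
TOTAL_VEHICLES_SD = 0.71


def older_driver_total(county: str) -> int:
    """Older-driver crash count of a county (PDO + injury/fatality)."""
    c = SEVERITY_COUNTS[county.lower()]
    return c["pdo"] + c["injury_fatality"]


def injury_share(county: str) -> float:
    """Percentage of older-driver crashes that were injury or fatality."""
    c = SEVERITY_COUNTS[county.lower()]
    return 100.0 * c["injury_fatality"] / (c["pdo"] + c["injury_fatality"])


def top_two_county_share() -> float:
    """Percentage of statewide crashes occurring in Clark County + Washoe."""
    return 100.0 * sum(COUNTY_CRASHES.values()) / STATE_TOTAL_CRASHES


def category_proportions(name: str) -> np.ndarray:
    """Printed percentages for one covariate, normalized to sum to 1."""
    p = np.asarray(CATEGORY_PERCENTAGES[name], dtype=float)
    return p / p.sum()
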