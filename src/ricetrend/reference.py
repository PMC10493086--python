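"""Reference metadata of the 1925–2019 Taichung long-term rice trial.

Cultivar cultivation spans, per-season experiment gap years, the
published cultivar grouping (four groups per season; the two-member
1977–1983 group is excluded from projections because it spans only
seven years inside the 1945–1983 group's period), and the published
cultivar-level percent regression coefficients used as worked-example
inputs for group summaries.

These are small tables of trial metadata, not measurement data; the
daily weather and yield measurements themselves are not shipped and are
either downloaded by the user or emulated by :mod:`ricetrend.simulate`.
"""

from __future__ import annotations

__all__ = [
    "CULTIVAR_SPANS",
    "GAP_YEARS",
    "REFERENCE_GROUPS",
    "REFERENCE_PCT_COEFFICIENTS",
    "ANALYSIS_PERIODS",
]

#: Overall (first, last) cultivation years per cultivar and season.
#: Interior interruptions are expressed by GAP_YEARS, which reproduces
#: every published multi-interval span exactly.
CULTIVAR_SPANS: dict[str, dict[str, tuple[int, int]]] = {
    "cool": {
        "NM": (1925, 1931),
        "TCS2": (1925, 1932),
        "BK": (1925, 1944),
        "TCS6": (1933, 1944),
        "WG": (1925, 1976),
        "BMF": (1945, 1976),
        "TC65": (1930, 1983),
        "TC150": (1945, 1983),
        "TCI1": (1964, 1983),
        "TCI3": (1977, 1983),
        "TA67": (1996, 2019),
        "TC189": (1996, 2019),
        "TCI10": (1996, 2019),
        "TJ9": (2000, 2019),
    },
    "warm": {
        "NM": (1925, 1931),
        "TCS2": (1925, 1944),
        "JG": (1925, 1944),
        "NY": (1925, 1944),
        "SJ": (1946, 1976),
        "SL": (1946, 1976),
        "TC65": (1930, 1983),
        "TC150": (1946, 1983),
        "TCI2": (1977, 1983),
        "TCI3": (1977, 1983),
        "TA67": (1996, 2019),
        "TC189": (1996, 2019),
        "TCI10": (1996, 2019),
        "TJ9": (2000, 2019),
    },
}

#: Years with no experiment, per season (applies to every cultivar).
GAP_YEARS: dict[str, frozenset[int]] = {
    "cool": frozenset(list(range(1948, 1952)) + list(range(1985, 1996))
                      + [2014, 2015, 2016]),
    "warm": frozenset([1945] + list(range(1947, 1952)) + list(range(1985, 1996))
                      + [2013, 2014, 2015]),
}

#: Published grouping of cultivars with overlapping cultivation periods.
REFERENCE_GROUPS: dict[str, list[dict]] = {
    "cool": [
        {"id": "1925-1944", "members": ["NM", "TCS2", "BK", "TCS6"],
         "period": (1925, 1944), "excluded": False},
        {"id": "1945-1983", "members": ["WG", "BMF", "TC65", "TC150"],
         "period": (1945, 1983), "excluded": False},
        {"id": "1977-1983", "members": ["TCI1", "TCI3"],
         "period": (1977, 1983), "excluded": True},
        {"id": "1996-2019", "members": ["TA67", "TC189", "TCI10", "TJ9"],
         "period": (1996, 2019), "excluded": False},
    ],
    "warm": [
        {"id": "1925-1944", "members": ["NM", "TCS2", "JG", "NY"],
         "period": (1925, 1944), "excluded": False},
        {"id": "1945-1983", "members": ["SJ", "SL", "TC65", "TC150"],
         "period": (1945, 1983), "excluded": False},
        {"id": "1977-1983", "members": ["TCI2", "TCI3"],
         "period": (1977, 1983), "excluded": True},
        {"id": "1996-2019", "members": ["TA67", "TC189", "TCI10", "TJ9"],
         "period": (1996, 2019), "excluded": False},
    ],
}

#: The three long-term analysis periods (the 1977–1983 group's period is
#: dropped together with that group).
ANALYSIS_PERIODS: list[tuple[int, int]] = [(1925, 1944), (1945, 1983), (1996, 2019)]

#: Published cultivar-level percent regression coefficients (% per unit
#: of ΔT °C, ΔDTR °C, ΔR mm, ΔS h), used as worked-example inputs for
#: group-summary checks.
REFERENCE_PCT_COEFFICIENTS: dict[str, dict[str, dict[str, float]]] = {
    "cool": {
        "NM":    {"T": 37.94,  "DTR": -61.38, "R": -2.12,  "S": -0.35},
        "TCS2":  {"T": 71.82,  "DTR": -69.51, "R": -3.80,  "S": -5.04},
        "BK":    {"T": 7.28,   "DTR": -3.99,  "R": -2.13,  "S": -6.61},
        "TCS6":  {"T": -8.00,  "DTR": -40.92, "R": -11.42, "S": -2.36},
        "WG":    {"T": 3.29,   "DTR": -2.14,  "R": 0.09,   "S": 0.80},
        "BMF":   {"T": 0.00,   "DTR": 2.68,   "R": -1.13,  "S": 4.21},
        "TC65":  {"T": 2.98,   "DTR": -5.90,  "R": -1.03,  "S": 1.25},
        "TC150": {"T": -1.30,  "DTR": -8.01,  "R": -0.68,  "S": 7.13},
        "TCI1":  {"T": 0.61,   "DTR": -10.64, "R": -1.33,  "S": 5.27},
        "TCI3":  {"T": -13.08, "DTR": -22.99, "R": 1.56,   "S": 8.82},
        "TA67":  {"T": -2.32,  "DTR": 24.94,  "R": 0.65,   "S": -9.46},
        "TC189": {"T": -6.29,  "DTR": 31.44,  "R": 1.47,   "S": -7.99},
        "TCI10": {"T": -3.88,  "DTR": 23.83,  "R": 0.14,   "S": -3.55},
        "TJ9":   {"T": -11.19, "DTR": 48.61,  "R": 0.92,   "S": -9.24},
    },
    "warm": {
        "NM":    {"T": -16.28, "DTR": -9.45,  "R": -4.00, "S": -29.87},
        "TCS2":  {"T": -15.55, "DTR": -2.51,  "R": -2.69, "S": -11.80},
        "JG":    {"T": -5.22,  "DTR": 1.50,   "R": -1.44, "S": -9.95},
        "NY":    {"T": -4.57,  "DTR": -1.95,  "R": -1.47, "S": -9.07},
        "SJ":    {"T": -4.30,  "DTR": -0.73,  "R": -0.06, "S": 4.66},
        "SL":    {"T": -8.85,  "DTR": -7.99,  "R": -3.71, "S": 1.13},
        "TC65":  {"T": -0.03,  "DTR": 2.77,   "R": -0.35, "S": 2.80},
        "TC150": {"T": -6.57,  "DTR": 0.27,   "R": -0.81, "S": 3.64},
        "TCI2":  {"T": -67.40, "DTR": 34.51,  "R": -9.34, "S": -13.88},
        "TCI3":  {"T": -46.75, "DTR": -64.65, "R": -1.41, "S": 58.85},
        "TA67":  {"T": 13.96,  "DTR": -3.49,  "R": -0.52, "S": -5.96},
        "TC189": {"T": -5.93,  "DTR": -8.56,  "R": -3.21, "S": -1.57},
        "TCI10": {"T": -0.98,  "DTR": -13.86, "R": -3.45, "S": -3.91},
        "TJ9":   {"T": -10.02, "DTR": -8.33,  "R": -4.09, "S": -8.83},
    },
}
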