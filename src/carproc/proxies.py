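"""Canonical metadata for the 16 ANS proxies.

Names, units, legal ranges, the log-transform set used before adjustment and
factor analysis, the reference loading sign pattern of the four latent domains,
and the expected monotone ordering of group means across the three BMI groups.
"""

from __future__ import annotations

# Column order is fixed throughout the package (CSV headers, matrices).
PROXY_NAMES: tuple[str, ...] = (
    "HR",
    "RR Mean",
    "RR TP",
    "RR LFa",
    "RR HFa",
    "RR LFnu",
    "RR HFnu",
    "RR LF/HF",
    "RR LFHz",
    "RR HFHz",
    "ΔRR LFnu",
    "α index",
    "SAP",
    "DAP",
    "SAP Mean",
    "SAP LFa",
)

N_PROXIES = len(PROXY_NAMES)

PROXY_UNITS: dict[str, str] = {
    "HR": "beat/min",
    "RR Mean": "ms",
    "RR TP": "ms^2",
    "RR LFa": "ms^2",
    "RR HFa": "ms^2",
    "RR LFnu": "nu",
    "RR HFnu": "nu",
    "RR LF/HF": "",
    "RR LFHz": "Hz",
    "RR HFHz": "Hz",
    "ΔRR LFnu": "nu",
    "α index": "ms/mmHg",
    "SAP": "mmHg",
    "DAP": "mmHg",
    "SAP Mean": "mmHg",
    "SAP LFa": "mmHg^2",
}

# Strictly positive by definition (variances, pressures, rates, gains).
POSITIVE_PROXIES: frozenset[str] = frozenset(
    {
        "HR",
        "RR Mean",
        "RR TP",
        "RR LFa",
        "RR HFa",
        "RR LF/HF",
        "α index",
        "SAP",
        "DAP",
        "SAP Mean",
        "SAP LFa",
    }
)

# Normalized-unit powers live in (0, 100).
NU_PROXIES: frozenset[str] = frozenset({"RR LFnu", "RR HFnu"})

# Center-frequency bands.
LF_BAND = (0.03, 0.14)
HF_BAND = (0.14, 0.45)

# Power-like, right-skewed proxies log-transformed before adjustment/EFA.
LOG_PROXIES: frozenset[str] = frozenset({"RR TP", "RR LFa", "RR HFa", "SAP LFa"})

# Reference sign pattern of the four latent domains: proxy -> loading sign.
# Only proxies expected to load at |loading| >= 0.5 appear.
DOMAIN_LABELS: tuple[str, ...] = ("oscillatory", "amplitude", "pressure", "pulse")

REFERENCE_SIGN_PATTERN: dict[str, dict[str, int]] = {
    "oscillatory": {"RR LFnu": +1, "RR LF/HF": +1, "RR HFnu": -1, "ΔRR LFnu": -1},
    "amplitude": {"RR TP": +1, "RR LFa": +1, "RR HFa": +1, "α index": +1},
    "pressure": {"SAP": +1, "DAP": +1, "SAP Mean": +1},
    "pulse": {"HR": +1, "RR Mean": -1},
}

# Monotone group-mean trends NW -> OW -> OB: +1 obese highest, -1 obese lowest.
# SAP LFa is exempt (its overweight mean is the highest).
TREND_DIRECTION: dict[str, int] = {
    "HR": +1,
    "RR Mean": -1,
    "RR TP": -1,
    "RR LFa": -1,
    "RR HFa": -1,
    "RR LFnu": +1,
    "RR HFnu": -1,
    "RR LF/HF": +1,
    "RR LFHz": -1,
    "RR HFHz": +1,
    "ΔRR LFnu": -1,
    "α index": -1,
    "SAP": +1,
    "DAP": +1,
    "SAP Mean": +1,
}

# Inter-proxy Pearson correlation targets the default generator is tuned to.
CORRELATION_TARGETS: dict[tuple[str, str], float] = {
    ("RR LFnu", "RR HFnu"): -0.945,
    ("RR LFnu", "ΔRR LFnu"): -0.711,
    ("RR HFnu", "ΔRR LFnu"): 0.683,
    ("α index", "RR LFHz"): 0.048,
    ("ΔRR LFnu", "RR LFa"): -0.052,
}

INDICATOR_COLUMNS: tuple[str, ...] = (
    "OSC_ind",
    "AMP_ind",
    "PRESS_ind",
    "PUL_ind",
    "alpha_aPRT",
    "BMI_aPRT",
    "ANSI",
)

# Indicator orientation with respect to the NW -> OB transition: the alternative
# direction used by default for the ordered trend tests.
INDICATOR_TREND_DIRECTION: dict[str, str] = {
    "OSC_ind": "decreasing",
    "AMP_ind": "decreasing",
    "PRESS_ind": "increasing",
    "PUL_ind": "increasing",
    "alpha_aPRT": "decreasing",
    "BMI_aPRT": "increasing",
    "ANSI": "decreasing",
}

DOMAIN_TO_INDICATOR: dict[str, str] = {
    "oscillatory": "OSC_ind",
    "amplitude": "AMP_ind",
    "pressure": "PRESS_ind",
    "pulse": "PUL_ind",
}
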