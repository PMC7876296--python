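"""Six-level strength-of-evidence grading of a nine-test battery.

Levels, strongest first: strong (all nine tests significant), almost_strong
(exactly one not significant), medium_strong (KW significant, at least one
median and one density test significant, and both trend tests significant),
medium (at least one of the KW/median/density family significant together with
at least one trend test), weak (exactly one of the two families contributes
significant results), insignificant (none).  Rules are applied in strict
precedence from strongest to weakest, which makes the classification
exhaustive and monotone in the significance pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from carproc.nptests import TestBattery

GRADE_LEVELS: tuple[str, ...] = (
    "insignificant",
    "weak",
    "medium",
    "medium_strong",
    "almost_strong",
    "strong",
)

GRADE_RANK: dict[str, int] = {name: i for i, name in enumerate(GRADE_LEVELS)}


@dataclass
class EvidenceGrade:
    level: str
    concordant: int
    kw_count: int
    median_count: int
    ba_count: int
    jt_count: int
    hn_count: int

    def __post_init__(self) -> None:
        total = self.kw_count + self.median_count + self.ba_count + self.jt_count + self.hn_count
        if total != self.concordant:
            raise ValueError("concordant count inconsistent with family counts")

    @property
    def rank(self) -> int:
        return GRADE_RANK[self.level]


def grade_pattern(kw: int, median: int, ba: int, jt: int, hn: int) -> str:
    """Grade a significance pattern given per-family significant-test counts
    (kw in 0..1, median in 0..3, ba in 0..3, jt in 0..1, hn in 0..1)."""
    if not (0 <= kw <= 1 and 0 <= median <= 3 and 0 <= ba <= 3 and 0 <= jt <= 1 and 0 <= hn <= 1):
        raise ValueError("family counts out of range")
    total = kw + median + ba + jt + hn
    location_family = kw + median + ba  # KW / median / BA side
    trend_family = jt + hn  # JT / HN side
    if total == 9:
        return "strong"
    if total == 8:
        return "almost_strong"
    if kw == 1 and median >= 1 and ba >= 1 and jt == 1 and hn == 1:
        return "medium_strong"
    if location_family >= 1 and trend_family >= 1:
        return "medium"
    if location_family >= 1 or trend_family >= 1:
        return "weak"
    return "insignificant"


def grade_evidence(battery: TestBattery) -> EvidenceGrade:
    """Map a nine-test battery onto the evidence-strength taxonomy."""
    kw = int(battery.kw.significant)
    median = sum(r.significant for r in battery.median_tests)
    ba = sum(r.significant for r in battery.ba_tests)
    jt = int(battery.jt.significant)
    hn = int(battery.hn.significant)
    level = grade_pattern(kw, median, ba, jt, hn)
    return EvidenceGrade(
        level=level,
        concordant=kw + median + ba + jt + hn,
        kw_count=kw,
        median_count=median,
        ba_count=ba,
        jt_count=jt,
        hn_count=hn,
    )


_OMNIBUS_SYMBOLS = {True: "≠", False: "="}
_TREND_SYMBOLS = {"increasing": "↗", "decreasing": "↘"}


def _cell(result) -> str:
    if result.test_name in ("JT", "HN"):
        return _TREND_SYMBOLS[result.direction] if result.significant else "="
    return _OMNIBUS_SYMBOLS[result.significant]


def _shade(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def synoptic_table(batteries: dict[str, TestBattery]) -> pd.DataFrame:
    """Synoptic summary: one row per indicator with the nine cell outcomes,
    significance shading, concordant count and grade."""
    if not batteries:
        raise ValueError("at least one battery required")
    rows = []
    for indicator, battery in batteries.items():
        grade = grade_evidence(battery)
        row: dict[str, object] = {"indicator": indicator}
        names = (
            "KW",
            "Mt NW-OW",
            "Mt NW-OB",
            "Mt OW-OB",
            "BA NW-OW",
            "BA NW-OB",
            "BA OW-OB",
            "JT",
            "HN",
        )
        for name, result in zip(names, battery.results):
            row[name] = _cell(result)
            row[f"{name} shade"] = _shade(result.p_value)
        row["concordant"] = grade.concordant
        row["grade"] = grade.level
        rows.append(row)
    return pd.DataFrame(rows).set_index("indicator")
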