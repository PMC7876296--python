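"""Reference demographics of the source clinical cohort.

Per-BMI-group counts, male/female splits, and age/BMI summary statistics of the
study population the default synthetic generator emulates.  Pooled quantities
(total n, male percentage, group percentages, pooled mean age) are derived from
the per-group cells, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass

BMI_GROUPS: tuple[str, ...] = ("NW", "OW", "OB")


@dataclass(frozen=True)
class GroupDemographics:
    """Per-group cells of the reference demographic table."""

    count: int
    n_male: int
    n_female: int
    bmi_mean: float
    bmi_sd: float
    age_mean: float
    age_sd: float


REFERENCE_DEMOGRAPHICS: dict[str, GroupDemographics] = {
    "NW": GroupDemographics(472, 163, 309, 21.33, 2.10, 32.85, 11.68),
    "OW": GroupDemographics(163, 89, 74, 26.91, 1.36, 40.03, 12.17),
    "OB": GroupDemographics(121, 31, 90, 38.28, 7.81, 42.26, 11.49),
}


def total_subjects() -> int:
    """Total cohort size, summed over the three BMI groups."""
    return sum(g.count for g in REFERENCE_DEMOGRAPHICS.values())


def total_males() -> int:
    """Total male count, summed over the three BMI groups."""
    return sum(g.n_male for g in REFERENCE_DEMOGRAPHICS.values())


def male_percentage() -> float:
    """Percentage of males in the pooled cohort."""
    return 100.0 * total_males() / total_subjects()


def group_percentage(group: str) -> float:
    """Percentage of subjects in ``group`` ('NW', 'OW' or 'OB')."""
    return 100.0 * REFERENCE_DEMOGRAPHICS[group].count / total_subjects()


def group_proportions() -> tuple[float, float, float]:
    """(NW, OW, OB) proportions of the pooled cohort."""
    n = total_subjects()
    return tuple(REFERENCE_DEMOGRAPHICS[g].count / n for g in BMI_GROUPS)  # type: ignore[return-value]


def pooled_mean_age() -> float:
    """Group-size-weighted average of the per-group mean ages."""
    num = sum(g.count * g.age_mean for g in REFERENCE_DEMOGRAPHICS.values())
    return num / total_subjects()
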