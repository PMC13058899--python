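"""Model dimensions: calendar years and age-class layout.

The life cycle is tracked over ages 2-7.  Fish recruit to the model as age-2
(ocean age-0) juveniles; ages 3-7 are the immature marine stages subject to
bycatch and natural mortality; maturation (and hence harvest and escapement)
happens at ages 4-7; bycatch is only observed at ages 3-6.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ModelDimensions:
    """Year and age bookkeeping for one model run.

    Arrays throughout the package are year-major with a full age axis covering
    ``ages`` (inclusive); entries outside a process's age range (e.g. harvest
    at age 3) are structurally zero.
    """

    first_year: int = 2003
    n_years: int = 21
    ages: tuple[int, int] = (2, 7)
    juvenile_age: int = 2
    immature_ages: tuple[int, int] = (3, 7)
    mature_ages: tuple[int, int] = (4, 7)
    bycatch_ages: tuple[int, int] = (3, 6)

    def __post_init__(self) -> None:
        lo, hi = self.ages
        if not (lo == self.juvenile_age and hi >= lo):
            raise ValueError("ages must start at the juvenile age")
        for sub in (self.immature_ages, self.mature_ages, self.bycatch_ages):
            if not (lo <= sub[0] <= sub[1] <= hi):
                raise ValueError(f"age range {sub} not contained in {self.ages}")
        if not (self.mature_ages[0] >= self.immature_ages[0]):
            raise ValueError("mature ages must be a subset of immature ages")
        if self.n_years < 3:
            raise ValueError("need at least 3 model years")

    # -- index helpers -----------------------------------------------------
    @property
    def n_ages(self) -> int:
        return self.ages[1] - self.ages[0] + 1

    @property
    def years(self) -> list[int]:
        return [self.first_year + t for t in range(self.n_years)]

    @property
    def age_list(self) -> list[int]:
        return list(range(self.ages[0], self.ages[1] + 1))

    @property
    def mature_age_list(self) -> list[int]:
        return list(range(self.mature_ages[0], self.mature_ages[1] + 1))

    @property
    def bycatch_age_list(self) -> list[int]:
        return list(range(self.bycatch_ages[0], self.bycatch_ages[1] + 1))

    def age_index(self, age: int) -> int:
        """Column index of a true age on the full age axis."""
        if not (self.ages[0] <= age <= self.ages[1]):
            raise ValueError(f"age {age} outside {self.ages}")
        return age - self.ages[0]

    def year_index(self, year: int) -> int:
        t = year - self.first_year
        if not (0 <= t < self.n_years):
            raise ValueError(f"year {year} outside model span")
        return t

    def cohort_of(self, year_idx: int, age: int) -> int:
        """Juvenile year-class index of fish aged ``age`` in year ``year_idx``.

        A fish at age a in year y was age 2 (a juvenile) a-2 years earlier, so
        the cohort label is y - (a - 2).  Negative values denote cohorts
        recruited before the first model year.
        """
        return year_idx - (age - self.juvenile_age)


DEFAULT_DIMS = ModelDimensions()
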