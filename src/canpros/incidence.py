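"""Population incidence tables by age band, calendar period, sex and site.

The table is the constraint target for the genetic model: genotype-specific
hazards are scaled so that the population-average incidence among survivors
reproduces these rates.  Rows hold half-open age bands ``[age_lo, age_hi)``
and optional half-open calendar-period bands ``[period_lo, period_hi)``; an
empty period means "all calendar years", which turns the table into a pure
birth-cohort/age lookup.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

COLUMNS = ["age_lo", "age_hi", "period_lo", "period_hi", "sex", "site", "rate"]


class IncidenceError(ValueError):
    """Malformed or inconsistent incidence table."""


class IncidenceTable:
    """Annual event rates per person-year, looked up by (age, birth_year).

    An individual's hazard at age ``t`` is read from the stratum covering
    calendar year ``birth_year + t``; with period-free rows this reduces to a
    pure age lookup.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise IncidenceError(f"incidence table missing columns: {missing}")
        df["period_lo"] = pd.to_numeric(df["period_lo"], errors="coerce").fillna(-np.inf)
        df["period_hi"] = pd.to_numeric(df["period_hi"], errors="coerce").fillna(np.inf)
        self.df = df[COLUMNS].reset_index(drop=True)
        self._validate()
        self._arr = {c: self.df[c].to_numpy() for c in
                     ("age_lo", "age_hi", "period_lo", "period_hi", "rate")}
        self._rate_cache = {}

    def _validate(self):
        df = self.df
        if (df["rate"] < 0).any():
            raise IncidenceError("rates must be >= 0")
        if (df["age_hi"] <= df["age_lo"]).any():
            raise IncidenceError("age bands must satisfy age_hi > age_lo")
        # within each (sex, site) and any pair of overlapping periods, age
        # bands must not overlap
        for (_, _), g in df.groupby(["sex", "site"]):
            rows = g[["age_lo", "age_hi", "period_lo", "period_hi"]].to_numpy()
            n = len(rows)
            for i in range(n):
                for j in range(i + 1, n):
                    a, b = rows[i], rows[j]
                    periods_overlap = a[2] < b[3] and b[2] < a[3]
                    ages_overlap = a[0] < b[1] and b[0] < a[1]
                    if periods_overlap and ages_overlap:
                        raise IncidenceError(
                            f"overlapping age bands {a[:2]} and {b[:2]} for "
                            f"overlapping calendar periods")

    @property
    def max_age(self):
        return int(self.df["age_hi"].replace(np.inf, 0).max())

    def sites(self, sex):
        return sorted(self.df.loc[self.df["sex"] == sex, "site"].unique())

    def rate(self, age, birth_year, sex="M", site="prostate"):
        """Rate per person-year at a single integer age."""
        return float(self.rates_for_cohort(birth_year, sex, site, age + 1)[age])

    def rates_for_cohort(self, birth_year, sex="M", site="prostate", max_age=None):
        """Annual rates for ages ``0 .. max_age-1`` of one birth cohort.

        Ages not covered by any band get rate 0 (e.g. below the youngest
        tabulated age).
        """
        if max_age is None:
            max_age = self.max_age
        key = (int(birth_year), sex, site, int(max_age))
        if key in self._rate_cache:
            return self._rate_cache[key]
        ages = np.arange(max_age)
        years = birth_year + ages
        sel = ((self.df["sex"] == sex) & (self.df["site"] == site)).to_numpy()
        a = self._arr
        m = (ages[None, :] >= a["age_lo"][sel, None]) & \
            (ages[None, :] < a["age_hi"][sel, None]) & \
            (years[None, :] >= a["period_lo"][sel, None]) & \
            (years[None, :] < a["period_hi"][sel, None])
        out = (m * a["rate"][sel, None]).sum(axis=0)
        self._rate_cache[key] = out
        return out

    def to_frame(self):
        return self.df.copy()

    @classmethod
    def from_bands(cls, bands, sex="M", site="prostate", period=(None, None)):
        """Build from ``[(age_lo, age_hi, rate), ...]`` for one sex/site."""
        rows = [dict(age_lo=a, age_hi=b, period_lo=period[0], period_hi=period[1],
                     sex=sex, site=site, rate=r) for a, b, r in bands]
        return cls(pd.DataFrame(rows))

    def combined(self, other: "IncidenceTable") -> "IncidenceTable":
        return IncidenceTable(pd.concat([self.df, other.df], ignore_index=True))


def read_incidence(path) -> IncidenceTable:
    """Read an incidence CSV with the declared header."""
    df = pd.read_csv(path, float_precision="round_trip")
    return IncidenceTable(df)


def write_incidence(table: IncidenceTable, path):
    df = table.to_frame()
    df = df.replace({np.inf: np.nan, -np.inf: np.nan})
    df.to_csv(path, index=False)


def incidence_from_csv_text(text: str) -> IncidenceTable:
    return IncidenceTable(pd.read_csv(io.StringIO(text)))
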