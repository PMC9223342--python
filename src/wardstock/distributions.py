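"""Empirical distributions estimated from ward event logs.

Five distributions drive the demand generator; all are estimated as the
ratio of favourable over possible cases in the logs:

* ``pd1(i | v)`` — probability that ``i`` patients are admitted on a day
  with vacancy ``v`` (empty beds after the day's discharges);
* ``pd2(class)`` — probability that a new patient belongs to a class;
* ``pd3(los | class)`` — length-of-stay distribution within a class;
* ``pd4(day | class, los)`` — day after admission on which an infection is
  first suspected, with an explicit ``NEVER`` outcome;
* ``pd5(lag | class, los)`` — days until the lab response / therapy switch.

The module also estimates per-drug Poisson rates for the drug-driven
competitor forecaster, the per-drug daily-consumption distributions feeding
the knapsack safety stock, and descriptive per-class statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

#: Support value of pd4 for patients who never develop an infection.
NEVER = "never"

_MASS_TOL = 1e-9


class EmpiricalDistribution:
    """A discrete distribution, optionally conditioned on a key.

    Internally a mapping ``key -> {value: mass}``; the unconditional case
    uses the single key ``None``.  Masses must sum to 1 for every key.
    """

    def __init__(self, table: Mapping):
        first = next(iter(table.values()), None)
        if first is not None and not isinstance(first, Mapping):
            table = {None: dict(table)}
        self.table = {k: dict(v) for k, v in table.items()}
        self.validate()

    def validate(self) -> None:
        for key, pmf in self.table.items():
            if not pmf:
                raise ValueError(f"empty pmf for key {key!r}")
            for v, p in pmf.items():
                if not (0.0 <= p <= 1.0 + _MASS_TOL):
                    raise ValueError(f"mass out of [0,1] for {key!r}:{v!r}")
            total = sum(pmf.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"masses for key {key!r} sum to {total}, not 1")

    @classmethod
    def from_counts(cls, counts: Mapping) -> "EmpiricalDistribution":
        first = next(iter(counts.values()), None)
        if first is not None and not isinstance(first, Mapping):
            counts = {None: dict(counts)}
        table = {}
        for key, c in counts.items():
            total = sum(c.values())
            if total > 0:
                table[key] = {v: n / total for v, n in c.items() if n > 0}
        return cls(table)

    @property
    def conditioned(self) -> bool:
        return list(self.table) != [None]

    def keys(self):
        return list(self.table)

    def support(self, key=None) -> list:
        return list(self.table[key])

    def mass(self, value, key=None) -> float:
        return self.table.get(key, {}).get(value, 0.0)

    def has_key(self, key) -> bool:
        return key in self.table

    def sample(self, rng: np.random.Generator, key=None):
        pmf = self.table[key]
        values = list(pmf)
        probs = np.fromiter(pmf.values(), dtype=float)
        probs = probs / probs.sum()
        return values[rng.choice(len(values), p=probs)]

    def mean(self, key=None) -> float:
        pmf = self.table[key]
        return sum(v * p for v, p in pmf.items())

    def nearest_smaller_key(self, key):
        """Largest numeric key <= ``key`` present in the table, if any."""
        numeric = sorted(k for k in self.table if isinstance(k, (int, float)) and k <= key)
        return numeric[-1] if numeric else None

    def total_variation(self, other: "EmpiricalDistribution", key=None) -> float:
        values = set(self.table.get(key, {})) | set(other.table.get(key, {}))
        return 0.5 * sum(abs(self.mass(v, key) - other.mass(v, key)) for v in values)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EmpiricalDistribution):
            return False
        if set(self.table) != set(other.table):
            return False
        for k, pmf in self.table.items():
            opmf = other.table[k]
            if set(pmf) != set(opmf):
                return False
            if any(abs(pmf[v] - opmf[v]) > 1e-12 for v in pmf):
                return False
        return True

    def __repr__(self) -> str:
        return f"EmpiricalDistribution({len(self.table)} keys)"

    # -- serialization -----------------------------------------------------
    # keys and support values may be None, strings, ints or tuples; they are
    # encoded as JSON-compatible tagged lists
    @staticmethod
    def _encode(obj):
        if isinstance(obj, tuple):
            return ["tuple", list(obj)]
        return ["scalar", obj]

    @staticmethod
    def _decode(obj):
        tag, value = obj
        return tuple(value) if tag == "tuple" else value

    def to_jsonable(self) -> list:
        return [
            [self._encode(key), [[self._encode(v), p] for v, p in pmf.items()]]
            for key, pmf in self.table.items()
        ]

    @classmethod
    def from_jsonable(cls, data: list) -> "EmpiricalDistribution":
        return cls(
            {
                cls._decode(key): {cls._decode(v): p for v, p in pmf}
                for key, pmf in data
            }
        )


# ---------------------------------------------------------------------------
# Event logs


PATIENT_COLUMNS = [
    "patient_id", "admission_day", "admission_type", "cls", "los",
    "death", "infection_day", "retest_lag", "year",
]


@dataclass
class AdmissionLog:
    """Per-day ward flow and per-patient outcomes.

    ``days`` has columns day, admissions, departures, occupancy, vacancy;
    ``patients`` has ``PATIENT_COLUMNS`` (``infection_day``/``retest_lag``
    may be NaN for patients without infections).  ``beds`` is the ward
    capacity in the logged period.
    """

    days: pd.DataFrame
    patients: pd.DataFrame
    beds: int

    def validate(self) -> None:
        """Check the occupancy recursion; raise naming the first bad day."""
        d = self.days
        if len(d) == 0:
            return
        occ_prev = np.concatenate([[0], d["occupancy"].to_numpy()[:-1]])
        expected_occ = occ_prev - d["departures"].to_numpy() + d["admissions"].to_numpy()
        expected_vac = self.beds - occ_prev + d["departures"].to_numpy()
        for i, day in enumerate(d["day"].to_numpy()):
            if d["occupancy"].iat[i] != expected_occ[i]:
                raise ValueError(f"inconsistent occupancy recursion on day {day}")
            if d["vacancy"].iat[i] != expected_vac[i]:
                raise ValueError(f"inconsistent vacancy on day {day}")
            if not 0 <= d["occupancy"].iat[i] <= self.beds:
                raise ValueError(f"occupancy out of [0, beds] on day {day}")


def estimate_pd1(log: AdmissionLog) -> EmpiricalDistribution:
    """Admissions-given-vacancy distribution from the daily flow log.

    ``pd1(i | v)`` = (#days with vacancy v and i admissions) / (#days with
    vacancy v).  Vacancies never observed are absent from the table.
    """
    log.validate()
    counts: dict[int, dict[int, int]] = {}
    for _, row in log.days.iterrows():
        v, i = int(row["vacancy"]), int(row["admissions"])
        counts.setdefault(v, {}).setdefault(i, 0)
        counts[v][i] += 1
    return EmpiricalDistribution.from_counts(counts)


def estimate_pd2_to_pd5(log: AdmissionLog) -> dict[str, EmpiricalDistribution]:
    """Class, LoS, infection-day and retest-lag distributions.

    Returns ``{"pd2": ..., "pd3": ..., "pd4": ..., "pd5": ...}``.  pd4 and
    pd5 are conditioned on ``(class, los)``; patients without an infection
    contribute the ``NEVER`` outcome to pd4 and are absent from pd5.
    """
    pats = log.patients
    if pats["cls"].isna().any():
        raise ValueError("patient with missing class label")
    c2: dict = {None: {}}
    c3: dict = {}
    c4: dict = {}
    c5: dict = {}
    for _, p in pats.iterrows():
        cls, los = p["cls"], int(p["los"])
        c2[None][cls] = c2[None].get(cls, 0) + 1
        c3.setdefault(cls, {}).setdefault(los, 0)
        c3[cls][los] += 1
        key = (cls, los)
        inf = p["infection_day"]
        outcome = NEVER if pd.isna(inf) else int(inf)
        c4.setdefault(key, {}).setdefault(outcome, 0)
        c4[key][outcome] += 1
        lag = p["retest_lag"]
        if not pd.isna(lag):
            c5.setdefault(key, {}).setdefault(int(lag), 0)
            c5[key][int(lag)] += 1
    return {
        "pd2": EmpiricalDistribution.from_counts(c2),
        "pd3": EmpiricalDistribution.from_counts(c3),
        "pd4": EmpiricalDistribution.from_counts(c4),
        "pd5": EmpiricalDistribution.from_counts(c5),
    }


# ---------------------------------------------------------------------------
# Drug-driven quantities


@dataclass(frozen=True)
class PoissonRates:
    """Expected daily doses per drug, for the drug-driven forecaster."""

    rates: Mapping[str, float]

    def __post_init__(self):
        if any(v < 0 for v in self.rates.values()):
            raise ValueError("rates must be non-negative")
        object.__setattr__(self, "rates", dict(self.rates))

    def __getitem__(self, drug_id: str) -> float:
        return self.rates[drug_id]


def estimate_poisson_rates(demand_log: pd.DataFrame) -> PoissonRates:
    """Mean daily doses per drug from a (days x drugs) demand table."""
    if len(demand_log) < 1:
        raise ValueError("demand log must cover at least one day")
    if (demand_log.to_numpy() < 0).any():
        raise ValueError("negative doses in demand log")
    return PoissonRates(demand_log.mean(axis=0).to_dict())


@dataclass
class ConsumptionDistribution:
    """Positive daily-consumption values and masses per drug.

    ``values[f]`` are the distinct positive daily dose totals observed for
    drug ``f`` (multiples of its posology) and ``masses[f]`` the fraction of
    days on which each was consumed.  Zero-consumption days carry the
    remaining (implicit) mass, so masses sum to <= 1.
    """

    values: dict[str, list[int]]
    masses: dict[str, list[float]]

    def items(self, drug_id: str) -> list[tuple[int, float]]:
        return list(zip(self.values.get(drug_id, []), self.masses.get(drug_id, [])))


def build_consumption_distribution(
    demand_log: pd.DataFrame, posologies: Mapping[str, int]
) -> ConsumptionDistribution:
    """Empirical daily-consumption distribution from a generator run.

    ``demand_log`` is a (days x drugs) dose table spanning H_P days; each
    positive entry must be a multiple of the drug's posology.
    """
    n_days = len(demand_log)
    if n_days < 1:
        raise ValueError("demand log must cover at least one day")
    values: dict[str, list[int]] = {}
    masses: dict[str, list[float]] = {}
    for f in demand_log.columns:
        col = demand_log[f].to_numpy()
        pos = posologies[f]
        bad = np.nonzero(col % pos)[0]
        if bad.size:
            raise ValueError(
                f"drug {f}: consumption {col[bad[0]]} on day {bad[0]} "
                f"is not a multiple of posology {pos}"
            )
        vals, counts = np.unique(col[col > 0], return_counts=True)
        values[f] = [int(v) for v in vals]
        masses[f] = [c / n_days for c in counts]
    return ConsumptionDistribution(values, masses)


# ---------------------------------------------------------------------------
# Descriptive statistics


def class_statistics(log: AdmissionLog) -> dict:
    """Per-class hospitalization counts, death and class probabilities.

    Returns ``{"per_class": DataFrame, "admission_type_shares": Series}``
    with death probability = deaths / NHosp within the class and class
    probability = NHosp / total.  Admission-type shares are computed the
    same way over the ``admission_type`` column.
    """
    pats = log.patients
    grouped = pats.groupby("cls", sort=True)
    nhosp = grouped.size()
    deaths = grouped["death"].sum()
    per_class = pd.DataFrame(
        {
            "nhosp": nhosp,
            "ndeath": deaths.astype(int),
            "death_prob": deaths / nhosp,
            "class_prob": nhosp / len(pats),
        }
    )
    shares = pats.groupby("admission_type", sort=True).size() / len(pats)
    return {"per_class": per_class, "admission_type_shares": shares}


def weighted_sd_quality(
    samples: pd.DataFrame, include_deaths: bool = True
) -> float:
    """Hospitalization-weighted average of per-(class, year) LoS SDs.

    ``samples`` needs columns cls, year, los, death.  Each (class, year)
    cell contributes its sample standard deviation (ddof=1; size-1 cells
    contribute 0) weighted by its number of hospitalizations.  With
    ``include_deaths`` unset, deceased patients are dropped before grouping.
    """
    df = samples if include_deaths else samples[~samples["death"].astype(bool)]
    if len(df) == 0:
        raise ValueError("no samples after filtering")
    total_w = 0.0
    acc = 0.0
    for _, cell in df.groupby(["cls", "year"]):
        w = len(cell)
        sd = float(cell["los"].std(ddof=1)) if w > 1 else 0.0
        acc += w * sd
        total_w += w
    return acc / total_w
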