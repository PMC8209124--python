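"""Synthetic individual-level cohorts with the statistical structure the
survival model assumes.

The generator emulates a long-term field study: individuals are born (or
immigrate) over a study window, die at Siler-distributed ages, may
permanently leave the monitored area (out-migration: Bernoulli event with a
gamma-distributed age above a class-specific minimum), are left-truncated at
study entry, and may have unknown birth dates or unknown fates.  A life-table
converter turns an lx column into pseudo-individual death records, mirroring
how period life tables are fitted with the same individual-level machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .siler import SilerParams, cumulative_hazard, survival

__all__ = [
    "OutMigrationModel",
    "IndividualRecord",
    "CohortConfig",
    "sample_ages_at_death",
    "simulate_cohort",
    "zoo_cohort",
    "lifetable_to_individuals",
    "synthetic_genus_params",
]

ORIGINS = ("natal", "immigrant")
FATES = ("dead", "out_migrated", "unknown", "censored")


@dataclass(frozen=True)
class OutMigrationModel:
    """Out-migration process for one dispersal class.

    pi          : Bernoulli probability of (permanent) out-migration
    gamma_shape : shape of the gamma distribution of dispersal ages
    gamma_rate  : rate (1/scale, per year) of that gamma distribution
    alpha       : minimum age at out-migration, years; dispersal age is
                  alpha + Gamma(shape, rate)
    dispersal_class : "natal" (first departure from the natal group) or
                  "immigrant" (secondary dispersal after immigration)
    """

    pi: float
    gamma_shape: float
    gamma_rate: float
    alpha: float = 0.0
    dispersal_class: str = "natal"

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError(f"pi must be in [0, 1], got {self.pi}")
        if self.gamma_shape <= 0 or self.gamma_rate <= 0:
            raise ValueError("gamma_shape and gamma_rate must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.dispersal_class not in ORIGINS:
            raise ValueError(f"dispersal_class must be one of {ORIGINS}")

    def dispersal_age_logpdf(self, age) -> np.ndarray:
        """Log-density of the age at out-migration (alpha + gamma)."""
        v = np.asarray(age, dtype=float) - self.alpha
        with np.errstate(divide="ignore"):
            return stats.gamma.logpdf(v, a=self.gamma_shape, scale=1.0 / self.gamma_rate)


@dataclass(frozen=True)
class IndividualRecord:
    """One animal's observation history.

    Calendar times are decimal years; ``birth`` is None when the birth date
    is unknown (to be imputed by the fitting model).
    """

    id: str
    birth: Optional[float]
    first_detect: float
    last_detect: float
    origin: str = "natal"
    fate: str = "dead"
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.last_detect < self.first_detect:
            raise ValueError(
                f"record {self.id}: last_detect {self.last_detect} precedes "
                f"first_detect {self.first_detect}"
            )
        if self.birth is not None and self.birth > self.first_detect:
            raise ValueError(f"record {self.id}: birth after first detection")
        if self.origin not in ORIGINS:
            raise ValueError(f"record {self.id}: origin must be one of {ORIGINS}")
        if self.fate not in FATES:
            raise ValueError(f"record {self.id}: fate must be one of {FATES}")

    @property
    def age_first(self) -> Optional[float]:
        return None if self.birth is None else self.first_detect - self.birth

    @property
    def age_last(self) -> Optional[float]:
        return None if self.birth is None else self.last_detect - self.birth


@dataclass(frozen=True)
class CohortConfig:
    """Settings for one simulated study population.

    n is the number of birth (or immigration) events drawn; records ending
    before the study window are discarded, so the returned cohort is smaller.
    ``unknown_fate_fraction`` relabels that fraction of out-migrations as
    fate-unknown; ``unknown_birth_fraction`` hides that fraction of birth
    dates.  Individuals still present at the window end are coded with
    ``end_of_study_fate`` ("unknown" keeps the two-branch likelihood;
    "censored" feeds the optional right-censoring branch of the fit).
    """

    n: int
    params: SilerParams
    outmig_natal: OutMigrationModel
    outmig_immigrant: Optional[OutMigrationModel] = None
    study_window: Tuple[float, float] = (2000.0, 2030.0)
    unknown_birth_fraction: float = 0.0
    unknown_fate_fraction: float = 0.0
    immigrant_fraction: float = 0.0
    burn_in_years: float = 50.0
    end_of_study_fate: str = "unknown"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        start, end = self.study_window
        if end - start < 1.0:
            raise ValueError("study window must span at least one year")
        for name in ("unknown_birth_fraction", "unknown_fate_fraction", "immigrant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.end_of_study_fate not in ("unknown", "censored"):
            raise ValueError("end_of_study_fate must be 'unknown' or 'censored'")


def _sample_death_ages(
    params: SilerParams, rng: np.random.Generator, n: int, entry_ages=None
) -> np.ndarray:
    """Inverse-CDF sampling of Siler death ages via root finding on U.

    Solves U(x) = U(entry) - log(1 - u) for u ~ Uniform(0,1); entry_ages
    (default 0) give left-truncated draws conditional on survival to entry.
    """
    u = rng.random(n)
    if entry_ages is None:
        entry_ages = np.zeros(n)
    targets = cumulative_hazard(params, entry_ages) - np.log1p(-u)
    out = np.empty(n)
    for i, (lo0, target) in enumerate(zip(np.asarray(entry_ages, float), targets)):
        f = lambda x: cumulative_hazard(params, x) - target
        hi = max(lo0, 1.0)
        for _ in range(200):
            if f(hi) > 0:
                break
            hi *= 2.0
        else:
            raise RuntimeError("failed to bracket the death-age root (hazard too small)")
        out[i] = optimize.brentq(f, lo0, hi, xtol=1e-10, rtol=1e-12)
    return out


def sample_ages_at_death(params: SilerParams, n: int, seed: int) -> np.ndarray:
    """i.i.d. ages at death from the Siler distribution; deterministic in seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return _sample_death_ages(params, rng, n)


def zoo_cohort(params: SilerParams, n: int, seed: int) -> List[IndividualRecord]:
    """Fully observed cohort: everyone followed from birth to death.

    Mirrors captive-population data where births and deaths are both
    recorded; all records have age at first detection 0 and fate "dead".
    """
    ages = sample_ages_at_death(params, n, seed)
    return [
        IndividualRecord(id=f"z{i}", birth=0.0, first_detect=0.0, last_detect=float(a))
        for i, a in enumerate(ages)
    ]


def simulate_cohort(config: CohortConfig) -> List[IndividualRecord]:
    """Simulate a field-study cohort with out-migration and truncation.

    Per individual: birth uniform over the study window extended left by
    ``burn_in_years``; with probability pi of its class the individual
    out-migrates at age alpha + Gamma(shape, rate), otherwise it dies at a
    Siler-distributed age.  Exit before the window start discards the record
    (left truncation); exit after the window end right-censors it at the end.
    Immigrants enter at a gamma-distributed age above their class minimum and
    are left-truncated at entry.
    """
    start, end = config.study_window
    root = np.random.SeedSequence(config.seed)
    rng_struct, rng_death, rng_outmig, rng_label = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    records: List[IndividualRecord] = []
    is_imm = rng_struct.random(config.n) < config.immigrant_fraction
    births = rng_struct.uniform(start - config.burn_in_years, end, size=config.n)
    for i in range(config.n):
        if is_imm[i] and config.outmig_immigrant is not None:
            om = config.outmig_immigrant
            origin = "immigrant"
            entry_age = om.alpha + rng_struct.gamma(om.gamma_shape, 1.0 / om.gamma_rate)
            entry_time = rng_struct.uniform(start, end)
            birth = entry_time - entry_age
        else:
            om = config.outmig_natal
            origin = "natal"
            birth = births[i]
            entry_age = max(0.0, start - birth)
            entry_time = birth + entry_age

        out_migrates = rng_outmig.random() < om.pi
        if out_migrates:
            exit_age = om.alpha + rng_outmig.gamma(om.gamma_shape, 1.0 / om.gamma_rate)
            if origin == "immigrant":
                for _ in range(100):
                    if exit_age > entry_age:
                        break
                    exit_age = om.alpha + rng_outmig.gamma(om.gamma_shape, 1.0 / om.gamma_rate)
                else:
                    out_migrates = False
            event = "out_migrated" if out_migrates else None
        if not out_migrates:
            exit_age = float(
                _sample_death_ages(config.params, rng_death, 1, [entry_age])[0]
            )
            event = "dead"

        exit_time = birth + exit_age
        if exit_time <= entry_time or exit_time <= start:
            continue  # left truncation: gone before observation began
        if exit_time > end:
            last, fate = end, config.end_of_study_fate
        else:
            last, fate = exit_time, event
        records.append(
            IndividualRecord(
                id=f"i{i}",
                birth=float(birth),
                first_detect=float(entry_time),
                last_detect=float(last),
                origin=origin,
                fate=fate,
            )
        )

    # relabel a fraction of out-migrations as fate-unknown, hide a fraction of births
    out: List[IndividualRecord] = []
    for rec in records:
        fate = rec.fate
        if fate == "out_migrated" and rng_label.random() < config.unknown_fate_fraction:
            fate = "unknown"
        birth = rec.birth
        if rng_label.random() < config.unknown_birth_fraction:
            birth = None
        if fate != rec.fate or birth is None:
            rec = IndividualRecord(
                id=rec.id,
                birth=birth,
                first_detect=rec.first_detect,
                last_detect=rec.last_detect,
                origin=rec.origin,
                fate=fate,
                sex=rec.sex,
            )
        out.append(rec)
    return out


def lifetable_to_individuals(
    ages: Sequence[float], lx: Sequence[float], radix: int, seed: int = 0
) -> List[IndividualRecord]:
    """Expand a period life table's lx column into pseudo-individuals.

    Each age class [ages[k], ages[k+1]) receives round(radix*(lx[k]-lx[k+1]))
    deaths placed uniformly within the class; the rounding residual goes to
    the open-ended last class (width taken from the previous class, or 1
    year).  Births are all at time 0 and every fate is "dead", so the result
    can be fitted with the fully observed (zoo-style) model.
    """
    ages = np.asarray(ages, dtype=float)
    lx = np.asarray(lx, dtype=float)
    if ages.ndim != 1 or ages.shape != lx.shape or len(ages) < 2:
        raise ValueError("ages and lx must be 1-d, equal length >= 2")
    if np.any(np.diff(ages) <= 0):
        raise ValueError("ages must be strictly increasing")
    if np.any(np.diff(lx) > 1e-12):
        k = int(np.argmax(np.diff(lx) > 1e-12)) + 1
        raise ValueError(f"lx increases at age {ages[k]}")
    if lx[0] <= 0:
        raise ValueError("lx[0] must be positive")
    lx = lx / lx[0]  # accept radix-scaled tables

    rng = np.random.default_rng(seed)
    counts = np.rint(radix * (lx[:-1] - lx[1:])).astype(int)
    last = radix - int(counts.sum())
    records: List[IndividualRecord] = []
    idx = 0
    for k, nk in enumerate(counts):
        lo, hi = ages[k], ages[k + 1]
        for a in rng.uniform(lo, hi, size=nk):
            records.append(
                IndividualRecord(id=f"lt{idx}", birth=0.0, first_detect=0.0, last_detect=float(a))
            )
            idx += 1
    if last > 0:
        width = ages[-1] - ages[-2] if len(ages) >= 2 else 1.0
        for a in rng.uniform(ages[-1], ages[-1] + width, size=last):
            records.append(
                IndividualRecord(id=f"lt{idx}", birth=0.0, first_detect=0.0, last_detect=float(a))
            )
            idx += 1
    return records


def synthetic_genus_params(
    n_populations: int = 6,
    base: Optional[SilerParams] = None,
) -> List[SilerParams]:
    """Parameter sets for a synthetic genus: shared ageing, varying early mortality.

    Within real genera most of the spread along the pace-shape line comes
    from infant/juvenile and age-independent mortality while the rate of
    ageing stays put.  The generated populations therefore share b0 and b1
    and interpolate a0 downward, a1 upward and c downward (log scale) from
    the highest-mortality to the lowest-mortality population, tracing a
    rising trajectory in the (e, eps) landscape.
    """
    if base is None:
        base = SilerParams(a0=-2.0, a1=1.0, c=0.01, b0=-5.0, b1=0.15)
    if n_populations < 2:
        raise ValueError("need at least two populations")
    t = np.linspace(0.0, 1.0, n_populations)
    out = []
    for ti in t:
        out.append(
            SilerParams(
                a0=-0.2 - 3.0 * ti,
                a1=0.6 + 1.0 * ti,
                c=float(np.exp(math.log(0.06) + ti * (math.log(0.005) - math.log(0.06)))),
                b0=base.b0,
                b1=base.b1,
            )
        )
    return out
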