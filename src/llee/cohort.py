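"""Synthetic admission-level cohorts with clustered hypoglycemia events.

The local dataset underlying a hospital-level glycemia evaluation is an
admission table in which a small fraction of inpatient admissions experience
one or more point-of-care blood-glucose (PoC-BGL) excursions.  Events are
categorised as severe hypoglycemia (<2.2 mmol/L), non-severe hypoglycemia
(2.2 to <4.0 mmol/L) or hyperglycemia (>15.0 mmol/L).  Hypoglycemia events
cluster within admissions: the count of events per affected admission is
modelled as a zero-truncated negative binomial (ZTNB), the minimal
two-parameter family that can match both the mean events per affected
admission and the share of affected admissions with two or more events.

:func:`fit_generator` moment-matches the ZTNB to baseline targets (affected
admissions, total events, multi-event share), :func:`generate_cohort` draws a
full cohort from a fitted configuration, and :func:`summarize_baseline`
recovers the audit-style summary statistics downstream stages consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "EventCategory",
    "GlycemicEvent",
    "Admission",
    "Cohort",
    "CohortConfig",
    "BaselineTargets",
    "BaselineSummary",
    "ConfigurationError",
    "InfeasibleTargetsError",
    "fit_generator",
    "generate_cohort",
    "summarize_baseline",
    "write_cohort_csv",
    "read_cohort_csv",
    "ztnb_pmf",
    "ztnb_moments",
]


class ConfigurationError(ValueError):
    """A cohort configuration field is outside its valid range."""


class InfeasibleTargetsError(ValueError):
    """Baseline targets cannot be met by the zero-truncated count family."""


class EventCategory(str, Enum):
    """Category of a PoC-BGL excursion.

    ``severe_hypo`` is BGL <2.2 mmol/L, ``nonsevere_hypo`` is 2.2 to
    <4.0 mmol/L; their union is "total hypoglycemia" (<4.0 mmol/L).
    ``hyper`` is BGL >15.0 mmol/L and is tracked only for the dysglycemia
    reporting criteria, never as an intervention outcome.
    """

    SEVERE_HYPO = "severe_hypo"
    NONSEVERE_HYPO = "nonsevere_hypo"
    HYPER = "hyper"

    @property
    def is_hypo(self) -> bool:
        return self is not EventCategory.HYPER


@dataclass
class GlycemicEvent:
    """One blood-glucose excursion during an admission.

    ``day`` is a 0-based admission-day index (day 0 = day of admission).
    ``prevented`` is always False at generation; the intervention engine
    sets it when an event is averted.
    """

    day: int
    category: EventCategory
    prevented: bool = False

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ConfigurationError(f"event day must be >= 0, got {self.day}")


@dataclass
class Admission:
    """An inpatient stay with its cohort flags and event history."""

    id: str
    length_of_stay: int
    adult: bool = True
    obstetric: bool = False
    surgical: bool = False
    icu: bool = False
    events: list[GlycemicEvent] = field(default_factory=list)
    coded_hac: bool = False

    def __post_init__(self) -> None:
        if self.length_of_stay < 1:
            raise ConfigurationError(
                f"length_of_stay must be >= 1, got {self.length_of_stay}"
            )
        self.events.sort(key=lambda e: e.day)
        for ev in self.events:
            if ev.day >= self.length_of_stay:
                raise ConfigurationError(
                    f"event day {ev.day} outside stay of {self.length_of_stay} days"
                )
        if self.coded_hac and not self.hypo_events:
            raise ConfigurationError(
                "coded_hac requires at least one hypoglycemia event"
            )

    @property
    def eligible(self) -> bool:
        """Adult, non-obstetric: the evaluation's eligible population."""
        return self.adult and not self.obstetric

    @property
    def hypo_events(self) -> list[GlycemicEvent]:
        return [e for e in self.events if e.category.is_hypo]

    @property
    def affected(self) -> bool:
        """True when the admission has at least one hypoglycemia event."""
        return any(e.category.is_hypo for e in self.events)


@dataclass
class Cohort:
    """A generated or loaded set of admissions plus provenance metadata."""

    admissions: list[Admission]
    config: "CohortConfig | None" = None

    def __len__(self) -> int:
        return len(self.admissions)

    def __iter__(self):
        return iter(self.admissions)


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    ``event_count_mean`` is the mean of the zero-truncated event-count
    distribution, i.e. mean hypoglycemia events per *affected* admission
    (>= 1; exactly 1 degenerates to one event each).  ``event_count_dispersion``
    is the negative-binomial size parameter r of the underlying count
    distribution; larger r approaches a zero-truncated Poisson.
    HAC fractions follow the coded-complication rule: coded HACs are a fixed
    share of admissions with at least one hypoglycemia event (24.0% across
    all patients, 25.5% among surgical patients).
    """

    n_admissions: int = 40_000
    p_affected: float = 0.0178
    event_count_mean: float = 2.702
    event_count_dispersion: float = 1.0
    severe_share: float = 0.10
    hyper_rate: float = 0.05
    # dysglycemia clusters within patients: affected admissions get their own
    # hyperglycemia rate.  0.75/day makes P(>=1 hyper event in a given day)
    # about 53%, the audited share of hypoglycemia events preceded by
    # hyperglycemia in the prior 24 h.
    hyper_rate_affected: float = 0.75
    los_mean: float = 5.0
    surgical_share: float = 0.35
    icu_share: float = 0.05
    obstetric_share: float = 0.10
    hac_fraction_all: float = 0.240
    hac_fraction_surgical: float = 0.255
    day_profile: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_admissions < 0:
            raise ConfigurationError(f"n_admissions must be >= 0, got {self.n_admissions}")
        for name in (
            "p_affected",
            "severe_share",
            "surgical_share",
            "icu_share",
            "obstetric_share",
            "hac_fraction_all",
            "hac_fraction_surgical",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.event_count_mean < 1.0:
            raise ConfigurationError(
                f"event_count_mean must be >= 1 (zero-truncated), got {self.event_count_mean}"
            )
        if self.event_count_dispersion <= 0:
            raise ConfigurationError(
                f"event_count_dispersion must be > 0, got {self.event_count_dispersion}"
            )
        if self.hyper_rate < 0:
            raise ConfigurationError(f"hyper_rate must be >= 0, got {self.hyper_rate}")
        if self.hyper_rate_affected < 0:
            raise ConfigurationError(
                f"hyper_rate_affected must be >= 0, got {self.hyper_rate_affected}"
            )
        if self.los_mean < 1.0:
            raise ConfigurationError(f"los_mean must be >= 1, got {self.los_mean}")
        if self.day_profile not in ("uniform", "front_loaded"):
            raise ConfigurationError(
                f"day_profile must be 'uniform' or 'front_loaded', got {self.day_profile!r}"
            )
        # non-surgical HAC rate implied by the all-patient and surgical fractions
        s = self.surgical_share
        if s < 1.0:
            p_ns = (self.hac_fraction_all - s * self.hac_fraction_surgical) / (1.0 - s)
            if not 0.0 <= p_ns <= 1.0:
                raise ConfigurationError(
                    "hac_fraction_all/hac_fraction_surgical imply a non-surgical "
                    f"HAC rate of {p_ns:.3f} outside [0, 1]"
                )


@dataclass
class BaselineTargets:
    """Printed baseline summaries the generator is moment-matched to.

    Defaults are the hospital-wide 2019 baseline: 641 admissions with
    hypoglycemia events, 1,732 events in total, and 63% of affected
    admissions experiencing two or more events (audit estimate).
    """

    n_affected: int = 641
    n_events: int = 1732
    p_multi: float = 0.63
    n_admissions: int = 40_000

    @property
    def mean_events(self) -> float:
        return self.n_events / self.n_affected


@dataclass
class BaselineSummary:
    """Audit-style summary of a cohort's hypoglycemia burden."""

    n_admissions: int
    n_affected: int
    n_events_total: int
    n_events_severe: int
    n_events_nonsevere: int
    n_events_hyper: int
    patient_days_with_hypo: int
    n_multi_event: int
    n_coded_hac: int

    @property
    def hac_fraction(self) -> float | None:
        """Coded HACs / affected admissions; None when no admission is affected."""
        if self.n_affected == 0:
            return None
        return self.n_coded_hac / self.n_affected

    @property
    def multi_event_share(self) -> float | None:
        if self.n_affected == 0:
            return None
        return self.n_multi_event / self.n_affected

    @property
    def mean_events_per_affected(self) -> float | None:
        if self.n_affected == 0:
            return None
        return self.n_events_total / self.n_affected

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in self.__dataclass_fields__}
        d["hac_fraction"] = self.hac_fraction
        d["multi_event_share"] = self.multi_event_share
        d["mean_events_per_affected"] = self.mean_events_per_affected
        return d


# ---------------------------------------------------------------------------
# zero-truncated negative binomial machinery


def _nb_p(mu: float, r: float) -> float:
    """scipy success-probability parameterisation from mean/dispersion."""
    return r / (r + mu)


def _one_minus_p0(mu: float, r: float) -> float:
    """1 - P(X=0) of the NB, stable for tiny r (log-series limit)."""
    q = mu / (r + mu)  # scipy's 1 - p
    return -math.expm1(r * math.log1p(-q))


def ztnb_pmf(k: np.ndarray | int, mu: float, r: float) -> np.ndarray:
    """PMF of the zero-truncated NB with untruncated mean ``mu``, size ``r``."""
    p = _nb_p(mu, r)
    k = np.asarray(k)
    return np.where(k >= 1, stats.nbinom.pmf(k, r, p), 0.0) / _one_minus_p0(mu, r)


def ztnb_moments(mu: float, r: float) -> tuple[float, float]:
    """(mean, P(X >= 2)) of the zero-truncated NB."""
    denom = _one_minus_p0(mu, r)
    mean = mu / denom
    q = mu / (r + mu)
    # NB pmf(1) = r * q * (1-q)^r
    p1 = r * q * math.exp(r * math.log1p(-q)) / denom
    return mean, 1.0 - p1


def _solve_mu(target_mean: float, r: float) -> float:
    """Untruncated mean whose zero-truncated mean equals ``target_mean``."""
    # solve in q = mu/(r+mu) in (0,1); the ZT mean is increasing in q
    def f(q: float) -> float:
        mu = r * q / (1.0 - q)
        return ztnb_moments(mu, r)[0] - target_mean

    q = optimize.brentq(f, 1e-15, 1.0 - 1e-12, xtol=1e-15)
    return r * q / (1.0 - q)


def fit_generator(targets: BaselineTargets, **config_overrides) -> CohortConfig:
    """Moment-match the generator to printed baseline counts.

    Solves the ZTNB (mean, dispersion) so the implied mean events per
    affected admission and P(two or more events | affected) both match the
    targets to 1e-6, and sets ``p_affected`` so the expected number of
    affected eligible admissions equals ``targets.n_affected``.

    Raises :class:`InfeasibleTargetsError` when the target pair lies outside
    the family's reachable range (e.g. mean < 1, or a multi-event share
    incompatible with the mean).
    """
    mean_t = targets.mean_events
    if mean_t < 1.0:
        raise InfeasibleTargetsError(
            f"mean events per affected admission is {mean_t:.4f} < 1"
        )
    base = dict(n_admissions=targets.n_admissions, seed=0)
    base.update(config_overrides)
    cfg = CohortConfig(**base)

    obst = cfg.obstetric_share
    n_eligible = targets.n_admissions * (1.0 - obst)
    if n_eligible <= 0 or targets.n_affected > n_eligible:
        raise InfeasibleTargetsError(
            f"{targets.n_affected} affected admissions exceed the "
            f"{n_eligible:.0f} eligible admissions"
        )
    p_affected = targets.n_affected / n_eligible

    if math.isclose(mean_t, 1.0, abs_tol=1e-12):
        if targets.p_multi > 1e-9:
            raise InfeasibleTargetsError(
                "mean of exactly 1 event forces P(>=2 events)=0, "
                f"but target is {targets.p_multi}"
            )
        return replace(cfg, p_affected=p_affected, event_count_mean=1.0)

    def pmulti_at(log_r: float) -> float:
        r = math.exp(log_r)
        mu = _solve_mu(mean_t, r)
        return ztnb_moments(mu, r)[1]

    lo, hi = -12.0, 12.0
    g = lambda log_r: pmulti_at(log_r) - targets.p_multi
    if g(lo) * g(hi) > 0:
        raise InfeasibleTargetsError(
            f"multi-event share {targets.p_multi} unreachable at mean {mean_t:.4f}: "
            f"attainable range is ({pmulti_at(lo):.4f}, {pmulti_at(hi):.4f})"
        )
    log_r = optimize.brentq(g, lo, hi, xtol=1e-12)
    r = math.exp(log_r)
    return replace(
        cfg,
        p_affected=p_affected,
        event_count_mean=mean_t,
        event_count_dispersion=r,
    )


def _sample_ztnb(rng: np.random.Generator, n: int, mean: float, r: float) -> np.ndarray:
    """Inverse-CDF sampling of the zero-truncated NB (deterministic in rng)."""
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if math.isclose(mean, 1.0, abs_tol=1e-12):
        return np.ones(n, dtype=np.int64)
    mu = _solve_mu(mean, r)
    p = _nb_p(mu, r)
    omp0 = _one_minus_p0(mu, r)
    u = (1.0 - omp0) + rng.random(n) * omp0
    return stats.nbinom.ppf(u, r, p).astype(np.int64)


# ---------------------------------------------------------------------------
# generation


def _event_days(
    rng: np.random.Generator, n_events: int, los: int, profile: str
) -> np.ndarray:
    if profile == "uniform" or los == 1:
        return rng.integers(0, los, n_events)
    # front-loaded: geometric decay over the stay (insulin-titration events
    # cluster early in an admission)
    w = 0.75 ** np.arange(los)
    return rng.choice(los, size=n_events, p=w / w.sum())


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a full admission cohort from ``config`` (deterministic per seed).

    Eligible (adult, non-obstetric) admissions become "affected" with
    probability ``p_affected``; each affected admission receives a ZTNB count
    of hypoglycemia events, severe with probability ``severe_share``, placed
    on days of the stay per ``day_profile``.  Hyperglycemia events arrive as
    a Poisson process at ``hyper_rate`` per admission-day.  Coded HACs are a
    Bernoulli flag per affected admission at the surgical or non-surgical
    rate implied by the two configured HAC fractions.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_admissions

    obstetric = rng.random(n) < config.obstetric_share
    surgical = rng.random(n) < config.surgical_share
    icu = rng.random(n) < config.icu_share
    los = 1 + rng.poisson(config.los_mean - 1.0, n)

    eligible = ~obstetric
    affected = eligible & (rng.random(n) < config.p_affected)
    counts = np.zeros(n, dtype=np.int64)
    counts[affected] = _sample_ztnb(
        rng, int(affected.sum()), config.event_count_mean, config.event_count_dispersion
    )
    hyper_rate = np.where(affected, config.hyper_rate_affected, config.hyper_rate)
    n_hyper = rng.poisson(hyper_rate * los)

    s = config.surgical_share
    p_ns = (
        (config.hac_fraction_all - s * config.hac_fraction_surgical) / (1.0 - s)
        if s < 1.0
        else config.hac_fraction_surgical
    )
    hac_p = np.where(surgical, config.hac_fraction_surgical, p_ns)
    coded_hac = affected & (rng.random(n) < hac_p)

    admissions: list[Admission] = []
    for i in range(n):
        events: list[GlycemicEvent] = []
        k = int(counts[i])
        if k:
            days = _event_days(rng, k, int(los[i]), config.day_profile)
            severe = rng.random(k) < config.severe_share
            for d, sev in zip(days, severe):
                events.append(
                    GlycemicEvent(
                        day=int(d),
                        category=EventCategory.SEVERE_HYPO
                        if sev
                        else EventCategory.NONSEVERE_HYPO,
                    )
                )
        h = int(n_hyper[i])
        if h:
            for d in rng.integers(0, int(los[i]), h):
                events.append(GlycemicEvent(day=int(d), category=EventCategory.HYPER))
        admissions.append(
            Admission(
                id=f"A{i:06d}",
                length_of_stay=int(los[i]),
                adult=True,
                obstetric=bool(obstetric[i]),
                surgical=bool(surgical[i]),
                icu=bool(icu[i]),
                events=events,
                coded_hac=bool(coded_hac[i]),
            )
        )
    return Cohort(admissions=admissions, config=config)


def summarize_baseline(cohort: Cohort | Sequence[Admission]) -> BaselineSummary:
    """Count the audit-style baseline statistics of a cohort."""
    admissions = list(cohort)
    if not admissions:
        raise ValueError("cohort is empty")
    n_sev = n_non = n_hyp = 0
    n_affected = n_multi = n_hac = 0
    patient_days = 0
    for adm in admissions:
        hypo_days = set()
        k = 0
        for ev in adm.events:
            if ev.category is EventCategory.SEVERE_HYPO:
                n_sev += 1
                k += 1
                hypo_days.add(ev.day)
            elif ev.category is EventCategory.NONSEVERE_HYPO:
                n_non += 1
                k += 1
                hypo_days.add(ev.day)
            else:
                n_hyp += 1
        if k >= 1:
            n_affected += 1
            if k >= 2:
                n_multi += 1
        if adm.coded_hac:
            n_hac += 1
        patient_days += len(hypo_days)
    return BaselineSummary(
        n_admissions=len(admissions),
        n_affected=n_affected,
        n_events_total=n_sev + n_non,
        n_events_severe=n_sev,
        n_events_nonsevere=n_non,
        n_events_hyper=n_hyp,
        patient_days_with_hypo=patient_days,
        n_multi_event=n_multi,
        n_coded_hac=n_hac,
    )


# ---------------------------------------------------------------------------
# CSV round trip (documented external schema)


def write_cohort_csv(cohort: Cohort, admissions_path, events_path) -> None:
    """Write the two-table CSV schema: one row per admission, one per event."""
    adm_rows = []
    ev_rows = []
    for adm in cohort:
        adm_rows.append(
            dict(
                admission_id=adm.id,
                adult=adm.adult,
                obstetric=adm.obstetric,
                surgical=adm.surgical,
                icu=adm.icu,
                length_of_stay=adm.length_of_stay,
                coded_hac=adm.coded_hac,
            )
        )
        for ev in adm.events:
            ev_rows.append(
                dict(
                    admission_id=adm.id,
                    day=ev.day,
                    category=ev.category.value,
                    prevented=ev.prevented,
                )
            )
    pd.DataFrame(adm_rows).to_csv(admissions_path, index=False)
    cols = ["admission_id", "day", "category", "prevented"]
    pd.DataFrame(ev_rows, columns=cols).to_csv(events_path, index=False)


def read_cohort_csv(admissions_path, events_path) -> Cohort:
    """Load a cohort from the documented two-table CSV schema."""
    adm_df = pd.read_csv(admissions_path)
    ev_df = pd.read_csv(events_path)
    by_adm: dict[str, list[GlycemicEvent]] = {}
    for row in ev_df.itertuples(index=False):
        by_adm.setdefault(str(row.admission_id), []).append(
            GlycemicEvent(
                day=int(row.day),
                category=EventCategory(row.category),
                prevented=bool(row.prevented),
            )
        )
    admissions = [
        Admission(
            id=str(row.admission_id),
            adult=bool(row.adult),
            obstetric=bool(row.obstetric),
            surgical=bool(row.surgical),
            icu=bool(row.icu),
            length_of_stay=int(row.length_of_stay),
            events=by_adm.get(str(row.admission_id), []),
            coded_hac=bool(row.coded_hac),
        )
        for row in adm_df.itertuples(index=False)
    ]
    return Cohort(admissions=admissions)
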