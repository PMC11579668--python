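"""Event-level intervention simulation with bootstrap resampling.

An intervention's effect is expressed as a relative risk (RR) per
hypoglycemia event, separately for the severe and non-severe channels.  The
prevention rule is stochastic: for each eligible event draw U ~ Uniform(0,1)
and mark the event prevented iff U > RR.  Eligibility combines the
intervention's target population (e.g. all adult non-obstetric admissions,
or surgical patients for a peri-operative team) with an optional dysglycemia
reporting rule - the virtual glycemic management service (vGMS) only reviews
patients flagged by two or more hyperglycemia events or one or more
hypoglycemia events in the previous 24 hours, so only events in flagged
admissions can be prevented.

Events within a patient are treated as independent.  This mirrors the
evaluation design; correlated responses would increase the number of
patients with *all* events prevented, so the fully-prevented counts here are
conservative.

Outputs are stabilised by resampling admissions with replacement
(:func:`bootstrap_run`, default 5,000 replicates) and reporting means and
percentile intervals of every reduction metric.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import yaml

from .cohort import Admission, Cohort, EventCategory, GlycemicEvent
from .costs import ResourceProfile, StaffLine

__all__ = [
    "OutcomeMeasure",
    "ReportingRule",
    "PublishedEffect",
    "InterventionSpec",
    "BootstrapSummary",
    "PreventionSummary",
    "TARGET_FILTERS",
    "apply_intervention",
    "evaluate_reporting_rule",
    "bootstrap_run",
    "summarize_prevention",
    "load_intervention_spec",
]

SCENARIOS = ("published", "realistic", "optimistic", "pessimistic")

# maximum events per cell axis in the joint severity histogram
_HIST_CAP = 10


class ParameterError(ValueError):
    """An effect or simulation parameter is outside its valid range."""


class OutcomeMeasure(str, Enum):
    """Outcome measure a published effect was reported on.

    ``events``: PoC-BGL measurements in the hypoglycemic range (the common
    measure - effects apply directly).  ``patient_days``: patient-days with
    one or more hypoglycemic events.  ``patients``: patients experiencing one
    or more hypoglycemic events during their admission.
    """

    EVENTS = "events"
    PATIENT_DAYS = "patient_days"
    PATIENTS = "patients"


def _filter_all_adult_nonobstetric(adm: Admission) -> bool:
    return adm.adult and not adm.obstetric


def _filter_surgical_incl_icu(adm: Admission) -> bool:
    return adm.adult and not adm.obstetric and (adm.surgical or adm.icu)


TARGET_FILTERS: dict[str, Callable[[Admission], bool]] = {
    "all_adult_nonobstetric": _filter_all_adult_nonobstetric,
    "surgical_incl_icu": _filter_surgical_incl_icu,
}


@dataclass(frozen=True)
class ReportingRule:
    """Dysglycemia criteria selecting admissions for daily service review.

    An event can be prevented only if, within ``window_days`` model days
    before it, the admission already had at least ``min_hyper`` hyperglycemia
    events or at least ``min_hypo`` hypoglycemia events.  The 24-hour window
    of the service's daily report is approximated by one model day.
    """

    min_hyper: int = 2
    min_hypo: int = 1
    window_days: int = 1

    def __post_init__(self) -> None:
        if self.min_hyper < 0 or self.min_hypo < 0 or self.window_days < 0:
            raise ParameterError("reporting rule thresholds must be >= 0")


@dataclass(frozen=True)
class PublishedEffect:
    """Published RR(s) and the outcome measure they were reported on."""

    outcome_measure: OutcomeMeasure
    rr_total_hypo: float
    rr_severe_hypo: float | None = None

    def __post_init__(self) -> None:
        _check_rr(self.rr_total_hypo, "rr_total_hypo")
        if self.rr_severe_hypo is not None:
            _check_rr(self.rr_severe_hypo, "rr_severe_hypo")


@dataclass
class InterventionSpec:
    """A candidate service intervention and everything needed to model it.

    ``elicited_rrs`` holds the working group's three-point estimates
    (most optimistic <= most realistic <= most pessimistic; smaller RR means
    larger effect) on the same outcome measure as the published effect.  A
    missing severe-channel RR means the severe channel inherits the
    total-hypoglycemia RR.
    """

    name: str
    target_population: str
    published_effect: PublishedEffect
    elicited_rrs: dict[str, dict[str, float | None]] = field(default_factory=dict)
    reporting_criteria: ReportingRule | None = None
    resources: ResourceProfile = field(default_factory=ResourceProfile)
    published_variants: tuple[float, ...] = ()
    # a per-event survey is triggered by each event that still occurs, so the
    # cost side charges survey time against the remaining events
    survey_per_event: bool = False

    def __post_init__(self) -> None:
        if self.target_population not in TARGET_FILTERS:
            raise ParameterError(
                f"unknown target_population {self.target_population!r}; "
                f"known: {sorted(TARGET_FILTERS)}"
            )
        for channel in ("total_hypo", "severe_hypo"):
            vals = [
                self.elicited_rrs.get(s, {}).get(channel)
                for s in ("optimistic", "realistic", "pessimistic")
            ]
            if all(v is not None for v in vals):
                opt, real, pess = vals
                if not (opt <= real <= pess):
                    raise ParameterError(
                        f"{self.name}: elicited {channel} RRs must satisfy "
                        f"optimistic <= realistic <= pessimistic, got {vals}"
                    )

    @property
    def target_filter(self) -> Callable[[Admission], bool]:
        return TARGET_FILTERS[self.target_population]

    def scenario_rrs(self, scenario: str) -> tuple[float, float]:
        """(rr_total, rr_severe) for a scenario, on the published measure.

        The severe channel inherits the total-hypoglycemia RR when no
        severe-specific estimate exists.
        """
        if scenario == "published":
            total = self.published_effect.rr_total_hypo
            severe = self.published_effect.rr_severe_hypo
        elif scenario in self.elicited_rrs:
            total = self.elicited_rrs[scenario].get("total_hypo")
            severe = self.elicited_rrs[scenario].get("severe_hypo")
            if total is None:
                raise ParameterError(
                    f"{self.name}: scenario {scenario!r} lacks a total-hypo RR"
                )
        else:
            raise ParameterError(
                f"{self.name}: scenario {scenario!r} not available "
                f"(have {['published', *self.elicited_rrs]})"
            )
        return float(total), float(total if severe is None else severe)

    def scenario_severe_explicit(self, scenario: str) -> bool:
        """True when the scenario carries its own severe-channel RR (rather
        than inheriting the total-hypoglycemia RR)."""
        if scenario == "published":
            return self.published_effect.rr_severe_hypo is not None
        return self.elicited_rrs.get(scenario, {}).get("severe_hypo") is not None


def _check_rr(rr: float, name: str = "rr") -> None:
    # rr = 0 is allowed as the "prevent everything" boundary
    if not 0.0 <= rr <= 1.0:
        raise ParameterError(f"{name} must be in [0, 1], got {rr}")


# ---------------------------------------------------------------------------
# reporting rule


def evaluate_reporting_rule(
    admission: Admission,
    event: GlycemicEvent | int,
    rule: ReportingRule,
) -> bool:
    """Would this event's admission be on the service report when it occurs?

    The history considered is every event strictly earlier in the
    admission's (day-ordered) event list whose day is within
    ``rule.window_days`` before the candidate's day.  History is evaluated
    against the pre-intervention record: an event prevented in the same
    simulation replicate still counts toward the criteria.
    """
    if isinstance(event, int):
        idx = event
        if not 0 <= idx < len(admission.events):
            raise IndexError(f"event index {idx} out of range")
    else:
        idx = next(
            (i for i, e in enumerate(admission.events) if e is event), None
        )
        if idx is None:
            raise ValueError("event does not belong to this admission")
    candidate = admission.events[idx]
    lo = candidate.day - rule.window_days
    n_hyper = n_hypo = 0
    for e in admission.events[:idx]:
        if e.day < lo:
            continue
        if e.category is EventCategory.HYPER:
            n_hyper += 1
        else:
            n_hypo += 1
    return n_hyper >= rule.min_hyper or n_hypo >= rule.min_hypo


# ---------------------------------------------------------------------------
# single application


def apply_intervention(
    cohort: Cohort,
    rr_severe: float,
    rr_nonsevere: float,
    target_filter: Callable[[Admission], bool] | None = None,
    reporting_rule: ReportingRule | None = None,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Apply the stochastic prevention rule; returns a new flagged cohort.

    For every hypoglycemia event of a targeted admission a uniform draw is
    consumed; the event is prevented iff it passes the reporting rule and
    the draw exceeds the RR of its severity channel (RR 0 prevents every
    eligible event; RR 1 prevents none).  Hyperglycemia events and events of
    non-targeted admissions are never prevented.  Consuming a draw per event
    regardless of eligibility couples runs that share an rng seed, so
    lowering an RR can only increase prevention (used by the monotonicity
    checks).
    """
    _check_rr(rr_severe, "rr_severe")
    _check_rr(rr_nonsevere, "rr_nonsevere")
    if rng is None:
        rng = np.random.default_rng()
    out = copy.deepcopy(cohort)
    for adm in out:
        targeted = target_filter is None or target_filter(adm)
        for idx, ev in enumerate(adm.events):
            if ev.category is EventCategory.HYPER:
                continue
            if not targeted:
                continue
            u = rng.random()
            if reporting_rule is not None and not evaluate_reporting_rule(
                adm, idx, reporting_rule
            ):
                continue
            rr = (
                rr_severe
                if ev.category is EventCategory.SEVERE_HYPO
                else rr_nonsevere
            )
            ev.prevented = (rr == 0.0) or (u > rr)
    return out


@dataclass
class PreventionSummary:
    """Reduction metrics read off one post-intervention cohort."""

    baseline_events_severe: int
    baseline_events_nonsevere: int
    events_prevented_severe: int
    events_prevented_nonsevere: int
    baseline_patients_affected: int
    patients_with_remaining: int
    patients_fully_prevented: int
    baseline_patient_days: int
    patient_days_with_remaining: int
    hac_reduction: float

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}


def summarize_prevention(cohort: Cohort, hac_fraction: float) -> PreventionSummary:
    """Count prevented/remaining events, patients and patient-days.

    The coded-HAC reduction follows the proportional rule: HACs are a fixed
    fraction of patients with at least one hypoglycemia event, so the
    reduction is ``hac_fraction`` times the drop in affected patients.
    """
    b_sev = b_non = p_sev = p_non = 0
    base_pat = rem_pat = 0
    base_days = rem_days = 0
    for adm in cohort:
        base_day_set = set()
        rem_day_set = set()
        k = k_rem = 0
        for ev in adm.events:
            if not ev.category.is_hypo:
                continue
            k += 1
            base_day_set.add(ev.day)
            severe = ev.category is EventCategory.SEVERE_HYPO
            if severe:
                b_sev += 1
            else:
                b_non += 1
            if ev.prevented:
                if severe:
                    p_sev += 1
                else:
                    p_non += 1
            else:
                k_rem += 1
                rem_day_set.add(ev.day)
        if k:
            base_pat += 1
            if k_rem:
                rem_pat += 1
        base_days += len(base_day_set)
        rem_days += len(rem_day_set)
    return PreventionSummary(
        baseline_events_severe=b_sev,
        baseline_events_nonsevere=b_non,
        events_prevented_severe=p_sev,
        events_prevented_nonsevere=p_non,
        baseline_patients_affected=base_pat,
        patients_with_remaining=rem_pat,
        patients_fully_prevented=base_pat - rem_pat,
        baseline_patient_days=base_days,
        patient_days_with_remaining=rem_days,
        hac_reduction=hac_fraction * (base_pat - rem_pat),
    )


# ---------------------------------------------------------------------------
# vectorised cohort index + bootstrap


class CohortIndex:
    """Flattened numpy view of a cohort's hypoglycemia events.

    Built once per (cohort, target filter, reporting rule); the bootstrap
    then only gathers slices and draws uniforms.  Event eligibility (target
    population membership and reporting criteria) is a property of the
    pre-intervention record, so it is precomputed per event.
    """

    def __init__(
        self,
        cohort: Cohort,
        target_filter: Callable[[Admission], bool] | None = None,
        reporting_rule: ReportingRule | None = None,
    ):
        severe: list[bool] = []
        elig: list[bool] = []
        day: list[int] = []
        counts = np.zeros(len(cohort.admissions), dtype=np.int64)
        max_day = 1
        for i, adm in enumerate(cohort):
            targeted = target_filter is None or target_filter(adm)
            for idx, ev in enumerate(adm.events):
                if not ev.category.is_hypo:
                    continue
                counts[i] += 1
                severe.append(ev.category is EventCategory.SEVERE_HYPO)
                day.append(ev.day)
                max_day = max(max_day, ev.day + 1)
                ok = targeted and (
                    reporting_rule is None
                    or evaluate_reporting_rule(adm, idx, reporting_rule)
                )
                elig.append(ok)
        self.n_admissions = len(cohort.admissions)
        self.counts = counts
        self.offsets = np.concatenate([[0], np.cumsum(counts)])
        self.severe = np.asarray(severe, dtype=bool)
        self.eligible = np.asarray(elig, dtype=bool)
        self.day = np.asarray(day, dtype=np.int64)
        self.day_stride = max_day

    def gather(self, sample: np.ndarray):
        """Row indices + occurrence ids for a resampled admission multiset."""
        lens = self.counts[sample]
        total = int(lens.sum())
        if total == 0:
            return np.zeros(0, np.int64), np.zeros(0, np.int64)
        starts = self.offsets[sample]
        nz = lens > 0
        starts, lens_nz = starts[nz], lens[nz]
        occ_ids = np.flatnonzero(nz)
        before = np.concatenate([[0], np.cumsum(lens_nz)])[:-1]
        rows = np.repeat(starts - before, lens_nz) + np.arange(total)
        occ = np.repeat(occ_ids, lens_nz)
        return rows, occ


@dataclass
class BootstrapSummary:
    """Per-replicate reduction metrics and their means/percentile intervals."""

    n_boot: int
    metrics: dict[str, np.ndarray]
    joint_hist_baseline: np.ndarray
    joint_hist_after: np.ndarray

    def mean(self, name: str) -> float:
        return float(np.mean(self.metrics[name]))

    def interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.metrics[name], [a, 1.0 - a])
        return float(lo), float(hi)

    def means(self) -> dict[str, float]:
        return {k: float(np.mean(v)) for k, v in self.metrics.items()}


def bootstrap_run(
    cohort: Cohort,
    spec: InterventionSpec,
    scenario: str,
    n_boot: int = 5000,
    seed: int | np.random.SeedSequence = 0,
    rr_override: tuple[float, float] | None = None,
    hac_fraction: float | None = None,
) -> BootstrapSummary:
    """Bootstrap the intervention: resample admissions, prevent, summarise.

    Admissions (with their event lists) are resampled with replacement,
    preserving within-patient clustering; each replicate applies the
    stochastic prevention rule with an independent random substream and the
    summary reports means and percentile intervals over replicates.

    ``rr_override`` supplies calibrated event-level (rr_severe, rr_nonsevere)
    when the spec's published measure is not ``events``; without it, scenario
    RRs reported on patient-days or patients cannot be applied directly and a
    :class:`ParameterError` is raised.
    """
    if n_boot < 1:
        raise ParameterError(f"n_boot must be >= 1, got {n_boot}")
    if not cohort.admissions:
        raise ValueError("cohort is empty")
    if rr_override is not None:
        rr_severe, rr_nonsevere = rr_override
    else:
        if spec.published_effect.outcome_measure is not OutcomeMeasure.EVENTS:
            raise ParameterError(
                f"{spec.name}: scenario RRs are on measure "
                f"{spec.published_effect.outcome_measure.value!r}; calibrate to "
                "event-level RRs first and pass rr_override"
            )
        rr_total, rr_severe = spec.scenario_rrs(scenario)
        rr_nonsevere = rr_total
    _check_rr(rr_severe, "rr_severe")
    _check_rr(rr_nonsevere, "rr_nonsevere")
    if hac_fraction is None:
        cfg = cohort.config
        if spec.target_population == "surgical_incl_icu":
            hac_fraction = cfg.hac_fraction_surgical if cfg else 0.255
        else:
            hac_fraction = cfg.hac_fraction_all if cfg else 0.240

    index = CohortIndex(cohort, spec.target_filter, spec.reporting_criteria)
    return _bootstrap_index(index, rr_severe, rr_nonsevere, n_boot, seed, hac_fraction)


def _bootstrap_index(
    index: CohortIndex,
    rr_severe: float,
    rr_nonsevere: float,
    n_boot: int,
    seed: int | np.random.SeedSequence,
    hac_fraction: float,
) -> BootstrapSummary:
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng = np.random.default_rng(ss)
    n_adm = index.n_admissions
    names = (
        "baseline_events_severe",
        "baseline_events_nonsevere",
        "events_prevented_severe",
        "events_prevented_nonsevere",
        "baseline_patients_affected",
        "patients_with_remaining",
        "patients_fully_prevented",
        "baseline_patient_days",
        "patient_days_with_remaining",
        "hac_reduction",
    )
    metrics = {k: np.zeros(n_boot) for k in names}
    hist_base = np.zeros((_HIST_CAP + 1, _HIST_CAP + 1))
    hist_after = np.zeros((_HIST_CAP + 1, _HIST_CAP + 1))

    for b in range(n_boot):
        sample = rng.integers(0, n_adm, n_adm)
        rows, occ = index.gather(sample)
        sev = index.severe[rows]
        elig = index.eligible[rows]
        u = rng.random(rows.size)
        rr = np.where(sev, rr_severe, rr_nonsevere)
        prevented = elig & ((u > rr) | (rr == 0.0))
        retained = ~prevented

        m = metrics
        m["baseline_events_severe"][b] = sev.sum()
        m["baseline_events_nonsevere"][b] = (~sev).sum()
        m["events_prevented_severe"][b] = (prevented & sev).sum()
        m["events_prevented_nonsevere"][b] = (prevented & ~sev).sum()

        if rows.size:
            bounds = np.flatnonzero(np.diff(occ, prepend=-1))
            rem = np.add.reduceat(retained.astype(np.int64), bounds)
            rem_sev = np.add.reduceat((retained & sev).astype(np.int64), bounds)
            rem_non = rem - rem_sev
            n_base_pat = bounds.size
            n_rem_pat = int((rem > 0).sum())

            daykey = occ * index.day_stride + index.day[rows]
            dbounds = np.flatnonzero(np.diff(daykey, prepend=-1))
            drem = np.add.reduceat(retained.astype(np.int64), dbounds)
            n_base_days = dbounds.size
            n_rem_days = int((drem > 0).sum())

            np.add.at(
                hist_base,
                (
                    np.minimum(rem_sev + np.add.reduceat(
                        (prevented & sev).astype(np.int64), bounds), _HIST_CAP),
                    np.minimum(rem_non + np.add.reduceat(
                        (prevented & ~sev).astype(np.int64), bounds), _HIST_CAP),
                ),
                1.0,
            )
            np.add.at(
                hist_after,
                (np.minimum(rem_sev, _HIST_CAP), np.minimum(rem_non, _HIST_CAP)),
                1.0,
            )
        else:
            n_base_pat = n_rem_pat = n_base_days = n_rem_days = 0

        m["baseline_patients_affected"][b] = n_base_pat
        m["patients_with_remaining"][b] = n_rem_pat
        m["patients_fully_prevented"][b] = n_base_pat - n_rem_pat
        m["baseline_patient_days"][b] = n_base_days
        m["patient_days_with_remaining"][b] = n_rem_days
        m["hac_reduction"][b] = hac_fraction * (n_base_pat - n_rem_pat)

    return BootstrapSummary(
        n_boot=n_boot,
        metrics=metrics,
        joint_hist_baseline=hist_base / n_boot,
        joint_hist_after=hist_after / n_boot,
    )


# ---------------------------------------------------------------------------
# YAML intervention specs


def _profile_from_dict(d: Mapping) -> ResourceProfile:
    staff = tuple(
        StaffLine(
            role=s["role"],
            fte=float(s["fte"]),
            annual_salary=None if s.get("annual_salary") is None else float(s["annual_salary"]),
            funded=bool(s.get("funded", False)),
        )
        for s in d.get("staff", [])
    )
    return ResourceProfile(
        staff=staff,
        once_off_hours=float(d.get("once_off_hours", 0.0)),
        per_cycle_components=dict(d.get("per_cycle_hours", {})),
    )


def load_intervention_spec(source: str | Path) -> InterventionSpec:
    """Load an intervention spec from YAML.

    ``source`` is a filesystem path, or the name of one of the shipped
    specs: ``root_cause_survey``, ``vgms``, ``gmt_pharmacist``.
    """
    path = Path(source)
    if not path.exists():
        pkg_file = importlib_resources.files("llee").joinpath("data", f"{source}.yaml")
        if not pkg_file.is_file():
            raise FileNotFoundError(f"no intervention spec at {source!r}")
        raw = yaml.safe_load(pkg_file.read_text())
    else:
        raw = yaml.safe_load(path.read_text())

    pub = raw["published_effect"]
    crit = raw.get("reporting_criteria")
    return InterventionSpec(
        name=raw["name"],
        target_population=raw["target_population"],
        published_effect=PublishedEffect(
            outcome_measure=OutcomeMeasure(pub["outcome_measure"]),
            rr_total_hypo=float(pub["rr_total_hypo"]),
            rr_severe_hypo=None
            if pub.get("rr_severe_hypo") is None
            else float(pub["rr_severe_hypo"]),
        ),
        elicited_rrs={
            k: dict(v) for k, v in (raw.get("elicited_rrs") or {}).items()
        },
        reporting_criteria=None
        if crit is None
        else ReportingRule(
            min_hyper=int(crit.get("min_hyper", 2)),
            min_hypo=int(crit.get("min_hypo", 1)),
            window_days=int(crit.get("window_days", 1)),
        ),
        resources=_profile_from_dict(raw.get("resources", {})),
        published_variants=tuple(raw.get("published_variants", ())),
        survey_per_event=bool(raw.get("survey_per_event", False)),
    )
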