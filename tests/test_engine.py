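"""Prevention engine: stochastic rule, reporting criteria, bootstrap."""

import numpy as np
import pytest
from scipy import stats

from llee.cohort import Cohort
from llee.engine import (
    InterventionSpec,
    OutcomeMeasure,
    ParameterError,
    PublishedEffect,
    ReportingRule,
    apply_intervention,
    bootstrap_run,
    evaluate_reporting_rule,
    load_intervention_spec,
    summarize_prevention,
)

from conftest import make_admission


def _n_prevented(cohort):
    return sum(ev.prevented for a in cohort for ev in a.events)


class TestApplyIntervention:
    def test_rr_one_prevents_nothing(self, dense_cohort, rng):
        out = apply_intervention(dense_cohort, 1.0, 1.0, rng=rng)
        assert _n_prevented(out) == 0

    def test_rr_zero_prevents_everything_eligible(self, dense_cohort, rng):
        out = apply_intervention(dense_cohort, 0.0, 0.0, rng=rng)
        for adm in out:
            for ev in adm.events:
                assert ev.prevented == ev.category.is_hypo

    def test_hyper_events_never_prevented(self, rng):
        cohort = Cohort([make_admission("h", [(0, "h"), (1, "h"), (1, "n")])])
        out = apply_intervention(cohort, 0.0, 0.0, rng=rng)
        flags = [(e.category.value, e.prevented) for e in out.admissions[0].events]
        assert flags == [("hyper", False), ("hyper", False), ("nonsevere_hypo", True)]

    def test_retained_fraction_within_binomial_bounds(self, rng):
        """10,000 non-severe events at RR 0.85: the retained count lies in the
        central 99.9% interval of Binomial(10000, 0.85)."""
        adms = [
            make_admission(f"b{i}", [(d, "n") for d in range(10)], los=10)
            for i in range(1000)
        ]
        out = apply_intervention(Cohort(adms), 0.85, 0.85, rng=rng)
        retained = 10_000 - _n_prevented(out)
        lo = stats.binom.ppf(0.0005, 10_000, 0.85)
        hi = stats.binom.ppf(0.9995, 10_000, 0.85)
        assert lo <= retained <= hi

    def test_rr_out_of_range_rejected(self, dense_cohort, rng):
        with pytest.raises(ParameterError):
            apply_intervention(dense_cohort, 1.2, 0.5, rng=rng)
        with pytest.raises(ParameterError):
            apply_intervention(dense_cohort, 0.5, -0.1, rng=rng)

    def test_target_filter_restricts_prevention(self, rng):
        surg = make_admission("s", [(0, "n")], surgical=True)
        med = make_admission("m", [(0, "n")], surgical=False)
        out = apply_intervention(
            Cohort([surg, med]), 0.0, 0.0,
            target_filter=lambda a: a.surgical, rng=rng,
        )
        flags = {a.id: a.events[0].prevented for a in out}
        assert flags == {"s": True, "m": False}

    def test_coupled_monotonicity_in_rr(self, dense_cohort):
        """With common random numbers, a smaller RR never prevents fewer
        events (scenario RRs 0.70 vs 0.82)."""
        strong = apply_intervention(
            dense_cohort, 0.70, 0.70, rng=np.random.default_rng(99)
        )
        weak = apply_intervention(
            dense_cohort, 0.82, 0.82, rng=np.random.default_rng(99)
        )
        for a_s, a_w in zip(strong, weak):
            for e_s, e_w in zip(a_s.events, a_w.events):
                assert e_s.prevented or not e_w.prevented  # weak ⇒ strong

    def test_conservation_by_severity(self, dense_cohort, rng):
        out = apply_intervention(dense_cohort, 0.5, 0.76, rng=rng)
        s = summarize_prevention(out, hac_fraction=0.24)
        base = summarize_prevention(dense_cohort, hac_fraction=0.24)
        assert s.baseline_events_severe == base.baseline_events_severe
        remaining_sev = sum(
            1
            for a in out
            for e in a.events
            if e.category.value == "severe_hypo" and not e.prevented
        )
        assert s.events_prevented_severe + remaining_sev == s.baseline_events_severe

    def test_closed_form_fully_prevented_expectation(self):
        """Mean patients-with-all-events-prevented over repeated applications
        matches sum over admissions of prod(1 - RR) within 3 SE."""
        rng = np.random.default_rng(7)
        adms = [
            make_admission(f"c{i}", [(0, "n")] * (1 + i % 3), los=4)
            for i in range(500)
        ]
        cohort = Cohort(adms)
        rr = 0.6
        expected = sum((1 - rr) ** len(a.hypo_events) for a in adms)
        reps = 150
        vals = []
        for _ in range(reps):
            out = apply_intervention(cohort, rr, rr, rng=rng)
            vals.append(summarize_prevention(out, 0.24).patients_fully_prevented)
        vals = np.asarray(vals, dtype=float)
        se = vals.std(ddof=1) / np.sqrt(reps)
        assert abs(vals.mean() - expected) <= 3 * se


class TestReportingRule:
    rule = ReportingRule(min_hyper=2, min_hypo=1, window_days=1)

    @pytest.mark.parametrize(
        "history,expected",
        [
            ([(0, "h"), (0, "h")], True),   # two hyper events the day before
            ([(0, "h")], False),            # one hyper is not enough
            ([], False),                    # first-ever event
            ([(0, "n")], True),             # one prior hypo suffices
            ([(0, "s")], True),
        ],
    )
    def test_prior_day_criteria(self, history, expected):
        adm = make_admission("r", history + [(1, "n")], los=5)
        idx = len(adm.events) - 1
        assert evaluate_reporting_rule(adm, idx, self.rule) is expected

    def test_events_outside_window_ignored(self):
        adm = make_admission("w", [(0, "n"), (3, "n")], los=5)
        assert evaluate_reporting_rule(adm, 1, self.rule) is False

    def test_same_day_earlier_event_counts(self):
        adm = make_admission("d", [(2, "n"), (2, "n")], los=5)
        assert evaluate_reporting_rule(adm, 0, self.rule) is False
        assert evaluate_reporting_rule(adm, 1, self.rule) is True

    def test_event_object_resolution(self):
        adm = make_admission("o", [(0, "n"), (1, "n")], los=5)
        assert evaluate_reporting_rule(adm, adm.events[1], self.rule) is True

    def test_never_eligible_admissions_untouched(self, rng):
        """Admissions that never meet the criteria have prevention probability
        exactly zero even at RR ~ 0."""
        # single first-ever events with no prior dysglycemia
        adms = [make_admission(f"n{i}", [(0, "n")]) for i in range(200)]
        out = apply_intervention(
            Cohort(adms), 0.0, 0.0, reporting_rule=self.rule, rng=rng
        )
        assert _n_prevented(out) == 0


class TestBootstrap:
    def _spec(self, **kw):
        base = dict(
            name="direct",
            target_population="all_adult_nonobstetric",
            published_effect=PublishedEffect(OutcomeMeasure.EVENTS, 1.0),
        )
        base.update(kw)
        return InterventionSpec(**base)

    def test_null_effect_yields_zero_reductions(self, dense_cohort):
        s = bootstrap_run(dense_cohort, self._spec(), "published", n_boot=1, seed=4)
        assert s.mean("events_prevented_severe") == 0
        assert s.mean("events_prevented_nonsevere") == 0
        assert s.mean("patients_fully_prevented") == 0
        assert s.mean("hac_reduction") == 0

    def test_single_event_cohort_fully_prevented_fraction(self):
        """With one event per admission, the expected share of patients with
        all events prevented is 1 - RR."""
        adms = [make_admission(f"s{i}", [(0, "n")]) for i in range(400)]
        cohort = Cohort(adms)
        rr = 0.7
        spec = self._spec(
            published_effect=PublishedEffect(OutcomeMeasure.EVENTS, rr)
        )
        s = bootstrap_run(cohort, spec, "published", n_boot=400, seed=8)
        frac = s.mean("patients_fully_prevented") / s.mean("baseline_patients_affected")
        arr = (
            s.metrics["patients_fully_prevented"] / s.metrics["baseline_patients_affected"]
        )
        se = arr.std(ddof=1) / np.sqrt(len(arr))
        assert abs(frac - (1 - rr)) <= 3 * se + 1e-9

    def test_scenario_monotonicity_with_shared_seed(self, dense_cohort):
        spec_lo = self._spec(published_effect=PublishedEffect(OutcomeMeasure.EVENTS, 0.70))
        spec_hi = self._spec(published_effect=PublishedEffect(OutcomeMeasure.EVENTS, 0.82))
        lo = bootstrap_run(dense_cohort, spec_lo, "published", n_boot=40, seed=21)
        hi = bootstrap_run(dense_cohort, spec_hi, "published", n_boot=40, seed=21)
        for metric in (
            "events_prevented_severe",
            "events_prevented_nonsevere",
            "patients_fully_prevented",
            "hac_reduction",
        ):
            assert np.all(lo.metrics[metric] >= hi.metrics[metric])

    def test_conservation_per_replicate(self, dense_cohort):
        spec = self._spec(published_effect=PublishedEffect(OutcomeMeasure.EVENTS, 0.8))
        s = bootstrap_run(dense_cohort, spec, "published", n_boot=30, seed=3)
        m = s.metrics
        assert np.all(
            m["baseline_patients_affected"]
            == m["patients_with_remaining"] + m["patients_fully_prevented"]
        )
        assert np.all(m["events_prevented_severe"] <= m["baseline_events_severe"])
        assert np.all(
            m["events_prevented_nonsevere"] <= m["baseline_events_nonsevere"]
        )

    def test_patient_day_measure_vs_object_summary(self, dense_cohort):
        """The vectorised bootstrap and the object-level summary agree on the
        baseline patient-day count when resampling is the identity."""
        base = summarize_prevention(dense_cohort, 0.24)
        spec = self._spec()
        s = bootstrap_run(dense_cohort, spec, "published", n_boot=60, seed=5)
        # bootstrap means fluctuate around the cohort values
        assert s.mean("baseline_patient_days") == pytest.approx(
            base.baseline_patient_days, rel=0.05
        )
        assert s.mean("baseline_patients_affected") == pytest.approx(
            base.baseline_patients_affected, rel=0.05
        )

    def test_non_event_measure_requires_override(self, dense_cohort):
        vgms = load_intervention_spec("vgms")
        with pytest.raises(ParameterError, match="calibrate"):
            bootstrap_run(dense_cohort, vgms, "realistic", n_boot=1, seed=0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_run(Cohort([]), self._spec(), "published", n_boot=1, seed=0)


class TestSpecFixtures:
    @pytest.mark.parametrize("name", ["root_cause_survey", "vgms", "gmt_pharmacist"])
    def test_shipped_specs_load(self, name):
        spec = load_intervention_spec(name)
        assert spec.name == name

    def test_vgms_elicited_three_points(self):
        spec = load_intervention_spec("vgms")
        assert spec.scenario_rrs("realistic") == (0.76, 0.50)
        assert spec.scenario_rrs("optimistic") == (0.70, 0.20)
        assert spec.scenario_rrs("pessimistic") == (0.82, 0.75)
        assert spec.reporting_criteria == ReportingRule(2, 1, 1)

    def test_severe_channel_inherits_total(self):
        spec = load_intervention_spec("root_cause_survey")
        assert spec.scenario_rrs("realistic") == (0.85, 0.85)
        assert not spec.scenario_severe_explicit("realistic")

    def test_elicited_ordering_enforced(self):
        with pytest.raises(ParameterError, match="optimistic"):
            InterventionSpec(
                name="bad",
                target_population="all_adult_nonobstetric",
                published_effect=PublishedEffect(OutcomeMeasure.EVENTS, 0.5),
                elicited_rrs={
                    "optimistic": {"total_hypo": 0.9},
                    "realistic": {"total_hypo": 0.8},
                    "pessimistic": {"total_hypo": 0.7},
                },
            )

    def test_unknown_scenario_rejected(self):
        spec = load_intervention_spec("gmt_pharmacist")
        with pytest.raises(ParameterError, match="realistic"):
            spec.scenario_rrs("realistic")
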