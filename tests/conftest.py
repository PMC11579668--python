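import numpy as np
import pytest

from llee.cohort import (
    Admission,
    BaselineTargets,
    Cohort,
    CohortConfig,
    EventCategory,
    GlycemicEvent,
    fit_generator,
    generate_cohort,
)


def make_admission(
    id: str,
    event_spec: list[tuple[int, str]],
    los: int = 10,
    **flags,
) -> Admission:
    """Build an admission from (day, category-shorthand) pairs.

    Shorthands: "s" severe hypo, "n" non-severe hypo, "h" hyper.
    """
    cats = {
        "s": EventCategory.SEVERE_HYPO,
        "n": EventCategory.NONSEVERE_HYPO,
        "h": EventCategory.HYPER,
    }
    events = [GlycemicEvent(day=d, category=cats[c]) for d, c in event_spec]
    return Admission(id=id, length_of_stay=los, events=events, **flags)


@pytest.fixture(scope="session")
def fitted_config() -> CohortConfig:
    """Generator config moment-matched to the printed hospital baseline."""
    return fit_generator(BaselineTargets())


@pytest.fixture(scope="session")
def baseline_cohort(fitted_config) -> Cohort:
    """Full-scale synthetic cohort at the fitted baseline (fixed seed)."""
    return generate_cohort(fitted_config)


@pytest.fixture(scope="session")
def dense_cohort() -> Cohort:
    """Small but event-dense cohort for engine/calibration statistics."""
    cfg = CohortConfig(
        n_admissions=1200,
        p_affected=0.5,
        event_count_mean=2.702,
        event_count_dispersion=1.0,
        severe_share=0.15,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def two_event_cohort() -> Cohort:
    """500 admissions, each with exactly two non-severe hypo events."""
    adms = [
        make_admission(f"T{i:03d}", [(0, "n"), (1, "n")], los=3) for i in range(500)
    ]
    return Cohort(admissions=adms)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
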